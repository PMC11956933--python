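"""CLAW: Boolean state encoding, transition estimation, pruning, zones.

A network *state* is the Boolean activation pattern of 10 encoded
populations (dSPN, iSPN, GPi, GPeP, Th for the left and right channels),
read as a 10-bit integer under the fixed bit order (MSB to LSB)

    dSPN-L, dSPN-R, iSPN-L, iSPN-R, GPi-L, GPi-R, GPeP-L, GPeP-R, Th-L, Th-R.

Under this order the pre-stimulus pattern (both GPi and both GPeP active)
is state 60, the launch states are 60-63, and the landmark deliberation
and commitment states carry the labels 55, 183, 191, 243, 247, 251, 535,
543, 575, 663, 759, 783.

Transition probabilities are estimated from the pooled per-trial state
sequences, with an explicit per-state "end" probability (the chance that
the state is the final one before the decision), and pruned with a
relative-gap rule: outgoing edges are kept in descending probability order
until the next edge is smaller by at least the gap fraction (default 25%)
of the previous one.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field

import networkx as nx
import numpy as np

from .binarize import BinaryTraceSet
from .populations import (
    AUX_POPULATIONS,
    ENCODED_POPULATIONS,
    POP_INDEX,
)

N_BITS = len(ENCODED_POPULATIONS)

#: Bit weight of each encoded population (MSB first).
BIT_VALUE = {name: 1 << (N_BITS - 1 - i) for i, name in enumerate(ENCODED_POPULATIONS)}


def encode_state(pattern) -> int:
    """Encode a Boolean 10-vector (in the fixed bit order) as an integer."""
    pattern = np.asarray(pattern)
    if pattern.shape != (N_BITS,):
        raise ValueError(f"pattern must have exactly {N_BITS} entries")
    label = 0
    for bit in pattern:
        label = (label << 1) | int(bool(bit))
    return label


def decode_state(label: int) -> np.ndarray:
    """Inverse of :func:`encode_state`."""
    if not 0 <= label < 2**N_BITS:
        raise ValueError(f"label must be in [0, {2**N_BITS - 1}]")
    return np.array([(label >> (N_BITS - 1 - i)) & 1 for i in range(N_BITS)],
                    dtype=bool)


def pattern_from_names(active: set[str] | list[str]) -> np.ndarray:
    """Boolean 10-vector with the named encoded populations set to 1."""
    active = set(active)
    unknown = active - set(ENCODED_POPULATIONS)
    if unknown:
        raise ValueError(f"not encoded populations: {sorted(unknown)}")
    return np.array([p in active for p in ENCODED_POPULATIONS])


def swap_label(label: int) -> int:
    """Mirror a state label across action channels (swap each L/R bit pair)."""
    bits = decode_state(label)
    swapped = bits.copy()
    for i in range(0, N_BITS, 2):
        swapped[i], swapped[i + 1] = bits[i + 1], bits[i]
    return encode_state(swapped)


# --------------------------------------------------------------------- #
# sequences
# --------------------------------------------------------------------- #

@dataclass
class StateSequence:
    """Per-trial sequence of state labels (one per 10 ms bin up to the
    decision), plus the STN/GPeA auxiliary bits and the outcome."""

    trial_id: int
    labels: np.ndarray          # int array, one label per bin
    aux_bits: np.ndarray        # (4, n_bins) Boolean, STN-L/R, GPeA-L/R
    choice: str
    decision_time: float


def extract_sequences(binary: BinaryTraceSet) -> list[StateSequence]:
    """Convert binarized trials into state-label sequences."""
    enc_idx = np.array([POP_INDEX[p] for p in ENCODED_POPULATIONS])
    aux_idx = np.array([POP_INDEX[p] for p in AUX_POPULATIONS])
    weights = np.array([BIT_VALUE[p] for p in ENCODED_POPULATIONS])
    out = []
    for t in binary.trials:
        if t.bits.shape[1] == 0:
            warnings.warn(f"trial {t.trial_id} has an empty trace; skipped")
            continue
        labels = weights @ t.bits[enc_idx].astype(int)
        out.append(
            StateSequence(
                trial_id=t.trial_id,
                labels=labels.astype(int),
                aux_bits=t.bits[aux_idx],
                choice=t.choice,
                decision_time=t.decision_time,
            )
        )
    return out


# --------------------------------------------------------------------- #
# transition estimation and pruning
# --------------------------------------------------------------------- #

@dataclass
class TransitionTable:
    """Raw transition counts between states, with per-state end counts."""

    counts: dict = field(default_factory=dict)      # (from, to) -> int
    end_counts: dict = field(default_factory=dict)  # state -> int
    occupancy: dict = field(default_factory=dict)   # state -> bins occupied
    mode: str = "per_change"

    def states(self) -> set[int]:
        s = set(self.end_counts) | set(self.occupancy)
        for a, b in self.counts:
            s.add(a)
            s.add(b)
        return s

    def probabilities(self) -> tuple[dict, dict]:
        """Normalize per source state over outgoing + end mass.

        Returns (edge probabilities {(from, to): p}, end probabilities
        {state: p}).
        """
        totals: dict[int, float] = dict(self.end_counts)
        for (a, _), n in self.counts.items():
            totals[a] = totals.get(a, 0) + n
        probs = {(a, b): n / totals[a] for (a, b), n in self.counts.items()}
        ends = {s: n / totals[s] for s, n in self.end_counts.items() if totals[s] > 0}
        return probs, ends


def estimate_transitions(sequences: list, mode: str = "per_change") -> TransitionTable:
    """Count state transitions over all sequences.

    ``per_change`` collapses dwell repetitions and counts only label-change
    events; ``per_bin`` counts every consecutive bin pair, including
    self-transitions.  In both modes each trial's final label contributes
    one end count.
    """
    if mode not in ("per_change", "per_bin"):
        raise ValueError(f"unknown mode {mode!r}")
    if not sequences:
        raise ValueError("need at least one sequence")
    tab = TransitionTable(mode=mode)
    for seq in sequences:
        labels = seq.labels
        for s in labels:
            tab.occupancy[int(s)] = tab.occupancy.get(int(s), 0) + 1
        if mode == "per_change":
            # collapse runs
            walk = [int(labels[0])]
            for s in labels[1:]:
                if int(s) != walk[-1]:
                    walk.append(int(s))
        else:
            walk = [int(s) for s in labels]
        for a, b in zip(walk[:-1], walk[1:]):
            tab.counts[(a, b)] = tab.counts.get((a, b), 0) + 1
        last = walk[-1]
        tab.end_counts[last] = tab.end_counts.get(last, 0) + 1
    return tab


@dataclass
class ClawGraph:
    """Pruned state-transition graph of the decision process."""

    graph: nx.DiGraph
    pruning_gap: float = 0.25
    mode: str = "per_change"

    def edge_probability(self, a: int, b: int) -> float:
        return self.graph.edges[a, b]["probability"]

    def end_probability(self, s: int) -> float:
        return self.graph.nodes[s].get("end_probability", 0.0)

    def states(self) -> list[int]:
        return sorted(self.graph.nodes)


def prune_edges(probs: list[float], gap: float) -> int:
    """Number of retained edges for a descending-sorted probability list.

    Retain edges 1..p for the smallest p at which
    (prob_p - prob_{p+1}) / prob_p >= gap; if no position qualifies,
    retain all.
    """
    for p in range(len(probs) - 1):
        if probs[p] <= 0:
            return p
        if (probs[p] - probs[p + 1]) / probs[p] >= gap:
            return p + 1
    return len(probs)


def prune_graph(table: TransitionTable, gap: float = 0.25) -> ClawGraph:
    """Build the pruned CLAW graph from a raw transition table."""
    probs, ends = table.probabilities()
    g = nx.DiGraph()
    for s in table.states():
        g.add_node(
            s,
            end_probability=float(ends.get(s, 0.0)),
            occupancy=int(table.occupancy.get(s, 0)),
        )
    outgoing: dict[int, list] = {}
    for (a, b), p in probs.items():
        outgoing.setdefault(a, []).append((p, b))
    for a, edges in outgoing.items():
        edges.sort(key=lambda e: (-e[0], e[1]))
        keep = prune_edges([p for p, _ in edges], gap)
        for p, b in edges[:keep]:
            g.add_edge(a, b, probability=float(p))
    return ClawGraph(graph=g, pruning_gap=gap, mode=table.mode)


# --------------------------------------------------------------------- #
# per-state statistics
# --------------------------------------------------------------------- #

@dataclass
class StateStats:
    state: int
    mean_dt: float
    n_left: int
    n_right: int
    kl_divergence: float       # nan when undefined
    kl_defined: bool
    aux_activation: dict       # population -> P(bit = 1 | state occupied)
    n_trials: int


def kl_from_histograms(p_counts: np.ndarray, q_counts: np.ndarray,
                       eps: float | None = None) -> float:
    """KL(P || Q) in nats between two count histograms on shared bins,
    with additive smoothing eps (default 1 / total count)."""
    p_counts = np.asarray(p_counts, dtype=float)
    q_counts = np.asarray(q_counts, dtype=float)
    if eps is None:
        total = p_counts.sum() + q_counts.sum()
        eps = 1.0 / total if total > 0 else 1.0
    p = p_counts + eps
    q = q_counts + eps
    p /= p.sum()
    q /= q.sum()
    return float(np.sum(p * np.log(p / q)))


def dt_kl_divergence(left_dts: np.ndarray, right_dts: np.ndarray,
                     n_bins: int = 10) -> tuple[float, bool]:
    """KL(left || right) of the choice-conditioned DT distributions over
    shared histogram bins.  Returns (value, defined flag); undefined when
    either side is empty."""
    left_dts = np.asarray(left_dts, dtype=float)
    right_dts = np.asarray(right_dts, dtype=float)
    if left_dts.size == 0 or right_dts.size == 0:
        return float("nan"), False
    pooled = np.concatenate([left_dts, right_dts])
    lo, hi = pooled.min(), pooled.max()
    if hi == lo:
        hi = lo + 1.0
    edges = np.linspace(lo, hi, n_bins + 1)
    lc, _ = np.histogram(left_dts, bins=edges)
    rc, _ = np.histogram(right_dts, bins=edges)
    return kl_from_histograms(lc, rc), True


def compute_state_stats(sequences: list) -> dict[int, StateStats]:
    """Per-state statistics over the trials that visit each state."""
    visits: dict[int, list] = {}          # state -> list of sequences
    aux_sum: dict[int, np.ndarray] = {}   # state -> summed aux bits
    aux_n: dict[int, int] = {}
    for seq in sequences:
        seen = set()
        for j, s in enumerate(seq.labels):
            s = int(s)
            if s not in seen:
                visits.setdefault(s, []).append(seq)
                seen.add(s)
            aux_sum[s] = aux_sum.get(s, np.zeros(len(AUX_POPULATIONS))) + seq.aux_bits[:, j]
            aux_n[s] = aux_n.get(s, 0) + 1
    stats = {}
    for s, seqs in visits.items():
        dts = np.array([q.decision_time for q in seqs])
        left = np.array([q.decision_time for q in seqs if q.choice == "left"])
        right = np.array([q.decision_time for q in seqs if q.choice == "right"])
        kl, defined = dt_kl_divergence(left, right)
        act = aux_sum[s] / aux_n[s]
        stats[s] = StateStats(
            state=s,
            mean_dt=float(dts.mean()),
            n_left=len(left),
            n_right=len(right),
            kl_divergence=kl,
            kl_defined=defined,
            aux_activation={p: float(a) for p, a in zip(AUX_POPULATIONS, act)},
            n_trials=len(seqs),
        )
    return stats


def attach_state_stats(graph: ClawGraph, stats: dict[int, StateStats]) -> None:
    for s, st in stats.items():
        if s in graph.graph.nodes:
            graph.graph.nodes[s]["mean_dt"] = st.mean_dt
            graph.graph.nodes[s]["n_left"] = st.n_left
            graph.graph.nodes[s]["n_right"] = st.n_right
            graph.graph.nodes[s]["kl_divergence"] = st.kl_divergence


# --------------------------------------------------------------------- #
# decision-time tertiles
# --------------------------------------------------------------------- #

@dataclass
class DtTertiles:
    cut_low: float
    cut_high: float

    def classify(self, dt: float) -> str:
        if dt <= self.cut_low:
            return "fast"
        if dt <= self.cut_high:
            return "intermediate"
        return "slow"


def dt_tertiles(decision_times) -> DtTertiles:
    """Equal-mass tertile cut points of the pooled decision times."""
    dts = np.sort(np.asarray(decision_times, dtype=float))
    if dts.size < 3:
        raise ValueError("need at least 3 decision times")
    if dts[0] == dts[-1]:
        warnings.warn("all decision times equal; tertiles are degenerate")
        return DtTertiles(cut_low=float(dts[0]), cut_high=float(dts[0]))
    c1 = float(np.quantile(dts, 1 / 3, method="inverted_cdf"))
    c2 = float(np.quantile(dts, 2 / 3, method="inverted_cdf"))
    return DtTertiles(cut_low=c1, cut_high=c2)


# --------------------------------------------------------------------- #
# zones
# --------------------------------------------------------------------- #

ZONES = ("I", "II", "III", "IV", "V", "VI")

#: Seed membership of the canonical zone partition.  Zone III seeds are the
#: printed left-arm commitment states; zone IV is their channel mirror.
_ZONE_SEEDS = {
    "I": {60, 61, 62, 63},
    "II": {55, 59, 183, 191, 123, 127},
    "III": {575, 543, 535, 663},
    "V": {247, 243, 251},
    "VI": {783},
}


def canonical_zone_seeds() -> dict[str, set[int]]:
    seeds = {z: set(s) for z, s in _ZONE_SEEDS.items()}
    seeds["IV"] = {swap_label(s) for s in seeds["III"]}
    return seeds


@dataclass
class ZonePartition:
    """Assignment of state labels to the six functional zones plus the
    zone-level transition structure."""

    state_to_zone: dict                      # label -> zone name or 'unassigned'
    zone_edges: dict = field(default_factory=dict)   # (zi, zj) -> probability
    zone_stay: dict = field(default_factory=dict)    # zone -> stay/absorb prob
    activation_table: dict = field(default_factory=dict)  # zone -> {pop: P(bit=1)}

    def zone_of(self, label: int) -> str:
        return self.state_to_zone.get(label, "unassigned")

    def members(self, zone: str) -> set[int]:
        return {s for s, z in self.state_to_zone.items() if z == zone}


def partition_zones(graph: ClawGraph, zone_map: dict[str, set] | None = None) -> ZonePartition:
    """Partition the CLAW states into zones.

    With no explicit map, the canonical partition is used: launch zone I
    {60..63}; initial-deliberation zone II; left/right commitment arms III
    and IV (seeds closed under retained outgoing edges that lead to
    decisions, with zone IV the channel mirror of zone III); second
    deliberation zone V; neutral-competition zone VI {783}.  States outside
    the map are 'unassigned'.
    """
    g = graph.graph
    if zone_map is not None:
        assign: dict[int, str] = {}
        for z, states in zone_map.items():
            for s in states:
                if s in assign:
                    raise ValueError(f"state {s} assigned twice "
                                     f"({assign[s]} and {z})")
                assign[s] = z
    else:
        seeds = canonical_zone_seeds()
        assign = {}
        for z, states in seeds.items():
            for s in states:
                if s in assign:
                    raise ValueError(f"state {s} in two zones ({assign[s]}, {z})")
                assign[s] = z
        # close the outer arms under retained successors that carry end
        # mass; a successor joins an arm only when the trials visiting it
        # lean to that arm's choice (left for III, right for IV), keeping
        # the closure consistent with the channel symmetry
        def _lean(t: int) -> str | None:
            nl = g.nodes[t].get("n_left")
            nr = g.nodes[t].get("n_right")
            if nl is None or nr is None or nl == nr:
                return None
            return "III" if nl > nr else "IV"

        changed = True
        while changed:
            changed = False
            for z in ("III", "IV"):
                frontier = [s for s, zz in assign.items() if zz == z and s in g]
                while frontier:
                    s = frontier.pop()
                    for t in g.successors(s):
                        if t in assign:
                            continue
                        reaches_end = graph.end_probability(t) > 0 or any(
                            u in assign and assign[u] in ("III", "IV")
                            for u in g.successors(t)
                        )
                        if reaches_end and _lean(t) == z:
                            assign[t] = z
                            frontier.append(t)
                            changed = True
            # bit-swap symmetry: the mirror of an arm state belongs to the
            # opposite arm
            for s, z in list(assign.items()):
                if z in ("III", "IV"):
                    m = swap_label(s)
                    if m not in assign:
                        assign[m] = "IV" if z == "III" else "III"
                        changed = True

    # zone-level transition aggregation, occupancy-weighted
    zone_flow: dict[tuple[str, str], float] = {}
    zone_out: dict[str, float] = {}
    for a, b, data in g.edges(data=True):
        za, zb = assign.get(a, "unassigned"), assign.get(b, "unassigned")
        w = g.nodes[a].get("occupancy", 1) * data["probability"]
        zone_flow[(za, zb)] = zone_flow.get((za, zb), 0.0) + w
        zone_out[za] = zone_out.get(za, 0.0) + w
    for s in g.nodes:
        za = assign.get(s, "unassigned")
        w = g.nodes[s].get("occupancy", 1) * g.nodes[s].get("end_probability", 0.0)
        zone_flow[(za, za)] = zone_flow.get((za, za), 0.0) + w
        zone_out[za] = zone_out.get(za, 0.0) + w

    edges = {}
    stay = {}
    for (za, zb), w in zone_flow.items():
        p = w / zone_out[za] if zone_out.get(za) else 0.0
        if za == zb:
            stay[za] = p
        else:
            edges[(za, zb)] = p

    # zone activation table from the state bit patterns, occupancy-weighted
    act: dict[str, dict] = {}
    for z in set(assign.values()):
        members = [s for s, zz in assign.items() if zz == z and s in g]
        if not members:
            continue
        occ = np.array([g.nodes[s].get("occupancy", 1) for s in members], dtype=float)
        if occ.sum() == 0:
            occ[:] = 1.0
        bits = np.array([decode_state(s) for s in members], dtype=float)
        probs = occ @ bits / occ.sum()
        act[z] = {p: float(v) for p, v in zip(ENCODED_POPULATIONS, probs)}

    return ZonePartition(
        state_to_zone=assign,
        zone_edges=edges,
        zone_stay=stay,
        activation_table=act,
    )


# --------------------------------------------------------------------- #
# export
# --------------------------------------------------------------------- #

def graph_to_json(graph: ClawGraph) -> dict:
    return {
        "pruning_gap": graph.pruning_gap,
        "mode": graph.mode,
        "nodes": [
            {"state": int(s), **{k: (None if isinstance(v, float) and np.isnan(v) else v)
                                 for k, v in d.items()}}
            for s, d in sorted(graph.graph.nodes(data=True))
        ],
        "edges": [
            {"from": int(a), "to": int(b), "probability": d["probability"]}
            for a, b, d in sorted(graph.graph.edges(data=True))
        ],
    }


def graph_from_json(d: dict) -> ClawGraph:
    g = nx.DiGraph()
    for node in d["nodes"]:
        attrs = {k: v for k, v in node.items() if k != "state" and v is not None}
        g.add_node(int(node["state"]), **attrs)
    for e in d["edges"]:
        g.add_edge(int(e["from"]), int(e["to"]), probability=e["probability"])
    return ClawGraph(graph=g, pruning_gap=d["pruning_gap"], mode=d["mode"])


def _dot_escape(v) -> str:
    return str(v).replace('"', r"\"")


def export_graph(graph: ClawGraph, path, fmt: str = "json") -> None:
    """Write the graph as lossless JSON, GraphML, or DOT.

    GraphML/DOT carry probabilities as edge attributes and the mean DT as a
    node attribute.
    """
    if graph.graph.number_of_nodes() == 0:
        raise ValueError("graph is empty")
    if fmt == "json":
        with open(path, "w") as fh:
            json.dump(graph_to_json(graph), fh, indent=1)
    elif fmt == "graphml":
        g = nx.DiGraph()
        for s, d in graph.graph.nodes(data=True):
            attrs = {k: float(v) for k, v in d.items()
                     if isinstance(v, (int, float)) and np.isfinite(v)}
            g.add_node(int(s), **attrs)
        for a, b, d in graph.graph.edges(data=True):
            g.add_edge(int(a), int(b), probability=float(d["probability"]))
        nx.write_graphml(g, path)
    elif fmt == "dot":
        lines = ["digraph claw {"]
        for s, d in sorted(graph.graph.nodes(data=True)):
            attrs = [f'end_probability="{d.get("end_probability", 0.0):.4f}"']
            if "mean_dt" in d and np.isfinite(d["mean_dt"]):
                attrs.append(f'mean_dt="{d["mean_dt"]:.1f}"')
            lines.append(f'  {s} [{", ".join(attrs)}];')
        for a, b, d in sorted(graph.graph.edges(data=True)):
            lines.append(f'  {a} -> {b} [label="{d["probability"]:.3f}"];')
        lines.append("}")
        with open(path, "w") as fh:
            fh.write("\n".join(lines) + "\n")
    else:
        raise ValueError(f"unknown format {fmt!r}")
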