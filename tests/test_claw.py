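"""State encoding, transition estimation, pruning, statistics, zones."""

import json

import networkx as nx
import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from claw_cbgt.binarize import BinaryTraceSet, binarize_traces, select_thresholds, build_histograms
from claw_cbgt.claw import (
    ClawGraph,
    StateSequence,
    canonical_zone_seeds,
    compute_state_stats,
    decode_state,
    dt_kl_divergence,
    dt_tertiles,
    encode_state,
    estimate_transitions,
    export_graph,
    extract_sequences,
    graph_from_json,
    graph_to_json,
    kl_from_histograms,
    partition_zones,
    pattern_from_names,
    prune_edges,
    prune_graph,
    swap_label,
)
from claw_cbgt.populations import ENCODED_POPULATIONS, POP_INDEX
from claw_cbgt.scripted import generate_scripted_traces


def _sequences(label_lists, choices=None, dts=None):
    choices = choices or ["left"] * len(label_lists)
    dts = dts or [100.0] * len(label_lists)
    return [
        StateSequence(
            trial_id=i, labels=np.array(ls, dtype=int),
            aux_bits=np.zeros((4, len(ls)), dtype=bool),
            choice=c, decision_time=d,
        )
        for i, (ls, c, d) in enumerate(zip(label_lists, choices, dts))
    ]


class TestEncoding:
    def test_extremes(self):
        assert encode_state(np.zeros(10, dtype=bool)) == 0
        assert encode_state(np.ones(10, dtype=bool)) == 1023

    def test_pre_stimulus_state(self):
        # both pallidal output populations active, everything else silent
        assert encode_state(
            pattern_from_names({"GPi-L", "GPi-R", "GPeP-L", "GPeP-R"})
        ) == 60

    def test_landmark_states(self):
        base = {"GPi-L", "GPi-R", "GPeP-L", "GPeP-R", "Th-L", "Th-R"}
        assert encode_state(pattern_from_names(base)) == 63
        assert encode_state(pattern_from_names(base | {"dSPN-L"})) == 575
        assert encode_state(pattern_from_names((base | {"dSPN-L"}) - {"GPi-L"})) == 543
        assert encode_state(
            pattern_from_names((base | {"iSPN-L"}) - {"GPeP-L"})) == 183

    def test_wrong_length_rejected(self):
        with pytest.raises(ValueError):
            encode_state(np.zeros(9, dtype=bool))

    @settings(deadline=None, max_examples=100)
    @given(st.integers(min_value=0, max_value=1023))
    def test_round_trip(self, label):
        assert encode_state(decode_state(label)) == label

    def test_round_trip_exhaustive(self):
        for label in range(1024):
            assert encode_state(decode_state(label)) == label

    def test_swap_label_involution(self):
        for label in range(0, 1024, 7):
            assert swap_label(swap_label(label)) == label
        assert swap_label(575) == 319  # dSPN-L <-> dSPN-R under the mirror


class TestExtractSequences:
    def test_scripted_walk_round_trip(self, scripted_thresholds):
        # replay of the initial-deliberation loop
        walk = [63, 55, 183, 191, 63]
        script = []
        for label in walk:
            names = {p for p, b in zip(ENCODED_POPULATIONS, decode_state(label)) if b}
            script.append((names, 2))
        rec = generate_scripted_traces(script, scripted_thresholds)
        thresholds = select_thresholds(build_histograms([rec]))
        for name, thr in scripted_thresholds.items():
            thresholds.entries[name].threshold = thr
        seqs = extract_sequences(binarize_traces([rec], thresholds))
        expect = [l for label in walk for l in [label, label]]
        assert seqs[0].labels.tolist() == expect
        # downstream transition counts match the scripted walk exactly
        table = estimate_transitions(seqs, mode="per_change")
        assert table.counts == {(63, 55): 1, (55, 183): 1, (183, 191): 1, (191, 63): 1}
        assert table.end_counts == {63: 1}

    def test_hand_built_trial(self):
        bits = np.zeros((18, 3), dtype=bool)
        bits[POP_INDEX["GPi-L"]] = [1, 1, 1]
        bits[POP_INDEX["Th-R"]] = [0, 1, 1]
        bits[POP_INDEX["dSPN-R"]] = [0, 0, 1]
        from claw_cbgt.binarize import BinaryTrial
        trial = BinaryTrial(bits=bits, choice="right", decision_time=30.0)
        seqs = extract_sequences(BinaryTraceSet(trials=[trial]))
        # manual base-2: GPi-L = 32, Th-R = 1, dSPN-R = 256
        assert seqs[0].labels.tolist() == [32, 33, 289]


class TestEstimateTransitions:
    def test_hand_count_per_change(self):
        seqs = _sequences([[60, 63, 575], [60, 63, 543]])
        table = estimate_transitions(seqs, mode="per_change")
        probs, ends = table.probabilities()
        assert probs[(60, 63)] == pytest.approx(1.0)
        assert probs[(63, 575)] == pytest.approx(0.5)
        assert probs[(63, 543)] == pytest.approx(0.5)
        assert ends[575] == pytest.approx(1.0)

    def test_per_bin_self_transitions(self):
        seqs = _sequences([[60, 60, 63]])
        table = estimate_transitions(seqs, mode="per_bin")
        probs, _ = table.probabilities()
        assert probs[(60, 60)] == pytest.approx(0.5)
        assert probs[(60, 63)] == pytest.approx(0.5)

    def test_single_state_sequence_ends(self):
        table = estimate_transitions(_sequences([[60]]))
        _, ends = table.probabilities()
        assert ends[60] == pytest.approx(1.0)

    def test_unknown_mode(self):
        with pytest.raises(ValueError):
            estimate_transitions(_sequences([[60]]), mode="bogus")

    @settings(deadline=None, max_examples=30)
    @given(
        st.lists(
            st.lists(st.integers(0, 7), min_size=1, max_size=12),
            min_size=1, max_size=10,
        ),
        st.sampled_from(["per_change", "per_bin"]),
    )
    def test_matches_brute_force_pair_count(self, label_lists, mode):
        table = estimate_transitions(_sequences(label_lists), mode=mode)
        # independent brute-force pair counting
        counts, ends = {}, {}
        for ls in label_lists:
            walk = list(ls)
            if mode == "per_change":
                walk = [walk[0]] + [b for a, b in zip(walk, walk[1:]) if b != a]
            for a, b in zip(walk, walk[1:]):
                counts[(a, b)] = counts.get((a, b), 0) + 1
            ends[walk[-1]] = ends.get(walk[-1], 0) + 1
        assert table.counts == counts
        assert table.end_counts == ends


class TestPruning:
    def test_gap_rule_examples(self):
        assert prune_edges([0.4, 0.3, 0.2, 0.1], 0.25) == 1
        assert prune_edges([0.25, 0.25, 0.25, 0.25], 0.25) == 4
        assert prune_edges([0.9], 0.25) == 1

    def test_probability_mass_invariants(self):
        seqs = _sequences([[1, 2, 3], [1, 2, 4], [1, 3], [1, 2, 3, 4]])
        table = estimate_transitions(seqs)
        probs, ends = table.probabilities()
        # pre-pruning mass sums to 1 per source state
        for s in table.states():
            out = sum(p for (a, _), p in probs.items() if a == s)
            assert out + ends.get(s, 0.0) == pytest.approx(1.0)
        graph = prune_graph(table, gap=0.25)
        for s in graph.states():
            retained = sum(
                d["probability"] for _, _, d in graph.graph.out_edges(s, data=True)
            )
            assert retained + graph.end_probability(s) <= 1.0 + 1e-9

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0.01, 1.0), min_size=1, max_size=8),
           st.floats(0.05, 0.9))
    def test_retained_prefix_respects_gap(self, raw, gap):
        probs = sorted((np.array(raw) / sum(raw)).tolist(), reverse=True)
        keep = prune_edges(probs, gap)
        assert 1 <= keep <= len(probs)
        for p in range(keep - 1):
            assert (probs[p] - probs[p + 1]) / probs[p] < gap
        if keep < len(probs):
            assert (probs[keep - 1] - probs[keep]) / probs[keep - 1] >= gap


class TestStateStats:
    def test_kl_identical_is_zero(self):
        assert kl_from_histograms(np.array([3, 5, 2]), np.array([3, 5, 2])) == pytest.approx(0.0)

    def test_kl_closed_form(self):
        # KL((.5,.5) || (.9,.1)) = .5 ln(.5/.9) + .5 ln(.5/.1)
        got = kl_from_histograms(np.array([0.5, 0.5]), np.array([0.9, 0.1]), eps=0.0)
        assert got == pytest.approx(0.5108, abs=1e-4)

    def test_kl_nonnegative(self, rng):
        for _ in range(20):
            p = rng.integers(0, 20, size=6)
            q = rng.integers(0, 20, size=6)
            if p.sum() == 0 or q.sum() == 0:
                continue
            assert kl_from_histograms(p, q) >= -1e-12

    def test_one_sided_state_flagged(self):
        kl, defined = dt_kl_divergence(np.array([100.0, 120.0]), np.array([]))
        assert not defined and np.isnan(kl)

    def test_stats_over_visiting_trials(self):
        seqs = _sequences(
            [[60, 63], [60, 63], [60, 61]],
            choices=["left", "right", "left"],
            dts=[100.0, 200.0, 300.0],
        )
        stats = compute_state_stats(seqs)
        assert stats[63].n_left == 1 and stats[63].n_right == 1
        assert stats[63].mean_dt == pytest.approx(150.0)
        assert stats[60].n_trials == 3
        assert stats[61].n_left == 1 and stats[61].n_right == 0

    def test_aux_activation_conditional_on_occupancy(self):
        seq = StateSequence(
            trial_id=0, labels=np.array([60, 60, 63]),
            aux_bits=np.array([[1, 0, 1], [0, 0, 0], [1, 1, 1], [0, 0, 1]],
                              dtype=bool),
            choice="left", decision_time=30.0,
        )
        stats = compute_state_stats([seq])
        assert stats[60].aux_activation["STN-L"] == pytest.approx(0.5)
        assert stats[63].aux_activation["STN-L"] == pytest.approx(1.0)
        assert stats[60].aux_activation["GPeA-R"] == pytest.approx(0.0)


class TestDtTertiles:
    def test_equal_count_split(self):
        t = dt_tertiles(range(1, 10))
        assert (t.cut_low, t.cut_high) == (3.0, 6.0)
        classes = [t.classify(x) for x in range(1, 10)]
        assert classes.count("fast") == 3
        assert classes.count("intermediate") == 3
        assert classes.count("slow") == 3

    def test_uniform_draws_balanced(self, rng):
        dts = rng.uniform(100, 900, size=300)
        t = dt_tertiles(dts)
        counts = {"fast": 0, "intermediate": 0, "slow": 0}
        for d in dts:
            counts[t.classify(d)] += 1
        for n in counts.values():
            assert abs(n - 100) <= 1

    def test_degenerate_all_equal(self):
        with pytest.warns(UserWarning, match="degenerate"):
            t = dt_tertiles([5.0] * 10)
        assert t.classify(5.0) == "fast"

    def test_too_few_rejected(self):
        with pytest.raises(ValueError):
            dt_tertiles([1.0, 2.0])


def _toy_graph():
    seqs = _sequences(
        [[60, 63, 575, 543], [60, 63, 183], [60, 62, 63, 783]],
        choices=["left", "left", "right"],
        dts=[100.0, 300.0, 200.0],
    )
    table = estimate_transitions(seqs)
    graph = prune_graph(table, gap=0.25)
    return graph


class TestZones:
    def test_canonical_membership(self):
        part = partition_zones(_toy_graph())
        assert part.zone_of(63) == "I"
        assert part.zone_of(60) == "I"
        assert part.zone_of(783) == "VI"
        assert part.zone_of(183) == "II"
        assert part.zone_of(543) == "III"
        assert part.zone_of(999) == "unassigned"

    def test_zone_seeds_mirror(self):
        seeds = canonical_zone_seeds()
        assert {swap_label(s) for s in seeds["III"]} == seeds["IV"]
        # zones II and V are channel-symmetric as sets
        assert {swap_label(s) for s in seeds["II"]} == seeds["II"]
        assert {swap_label(s) for s in seeds["V"]} == seeds["V"]

    def test_partition_is_disjoint(self):
        part = partition_zones(_toy_graph())
        seen = {}
        for s, z in part.state_to_zone.items():
            assert s not in seen
            seen[s] = z

    def test_duplicate_explicit_map_rejected(self):
        g = _toy_graph()
        with pytest.raises(ValueError, match="twice"):
            partition_zones(g, zone_map={"I": {60, 63}, "II": {63}})
        part = partition_zones(g, zone_map={"I": {60, 63}})
        assert part.zone_of(60) == "I"
        assert part.zone_of(575) == "unassigned"

    def test_zone_stay_and_edges_are_probabilities(self):
        part = partition_zones(_toy_graph())
        for p in list(part.zone_edges.values()) + list(part.zone_stay.values()):
            assert 0.0 <= p <= 1.0 + 1e-9


class TestExport:
    def test_json_round_trip_identity(self, tmp_path):
        g = _toy_graph()
        path = tmp_path / "g.json"
        export_graph(g, path, "json")
        loaded = graph_from_json(json.loads(path.read_text()))
        assert graph_to_json(loaded) == graph_to_json(g)

    def test_dot_edge_count(self, tmp_path):
        g = _toy_graph()
        path = tmp_path / "g.dot"
        export_graph(g, path, "dot")
        text = path.read_text()
        assert text.count("->") == g.graph.number_of_edges()

    def test_graphml_parses_and_round_trips(self, tmp_path):
        from lxml import etree
        g = _toy_graph()
        path = tmp_path / "g.graphml"
        export_graph(g, path, "graphml")
        root = etree.parse(str(path)).getroot()
        assert root.tag.endswith("graphml")
        back = nx.read_graphml(path)
        assert back.number_of_nodes() == g.graph.number_of_nodes()
        assert back.number_of_edges() == g.graph.number_of_edges()

    def test_unknown_format_rejected(self, tmp_path):
        with pytest.raises(ValueError):
            export_graph(_toy_graph(), tmp_path / "x", "pdf")

    def test_empty_graph_rejected(self, tmp_path):
        empty = ClawGraph(graph=nx.DiGraph())
        with pytest.raises(ValueError):
            export_graph(empty, tmp_path / "x.json", "json")
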