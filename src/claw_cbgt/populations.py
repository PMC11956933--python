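"""Population identities and circuit connectivity of the CBGT model.

The network has 10 cell types.  Eight of them (Cx, dSPN, iSPN, GPeP, GPeA,
STN, GPi, Th) are duplicated into a left and a right action channel; the
cortical interneurons (CxI) and the striatal fast-spiking interneurons (FSI)
are shared across channels, giving 18 population instances in total.

Connectivity is expressed at the cell-type level with a fixed sign table
(excitatory/inhibitory) and expanded to the 18 instances by the channel
rule: lateralized -> lateralized connections stay within a channel, while
connections to or from a shared population touch both channels.  The three
classical sub-circuits are covered: the direct pathway
(Cx -> dSPN -> GPi -> Th), the indirect pathway
(Cx -> iSPN -> GPeP -> STN/GPi) and the pallidostriatal pathway
(STN -> GPeA -> striatum).
"""

from __future__ import annotations

from dataclasses import dataclass

LATERALIZED = ("Cx", "dSPN", "iSPN", "GPeP", "GPeA", "STN", "GPi", "Th")
SHARED = ("CxI", "FSI")

#: Canonical order of the 18 population instances (row/column order of all
#: rate matrices in the package).
ALL_POPULATIONS: tuple[str, ...] = (
    "Cx-L", "Cx-R", "CxI", "FSI",
    "dSPN-L", "dSPN-R", "iSPN-L", "iSPN-R",
    "GPeP-L", "GPeP-R", "GPeA-L", "GPeA-R",
    "STN-L", "STN-R", "GPi-L", "GPi-R",
    "Th-L", "Th-R",
)

POP_INDEX = {name: i for i, name in enumerate(ALL_POPULATIONS)}

#: The 10 populations whose Boolean activity defines a CLAW state, in the
#: fixed bit order (most significant bit first).  This order reproduces the
#: published integer labels of all landmark states (60, 63, 183, 575, ...).
ENCODED_POPULATIONS: tuple[str, ...] = (
    "dSPN-L", "dSPN-R", "iSPN-L", "iSPN-R",
    "GPi-L", "GPi-R", "GPeP-L", "GPeP-R",
    "Th-L", "Th-R",
)

#: STN and GPeA bits are tracked alongside states for the per-state
#: activation statistics, but do not enter the state label.
AUX_POPULATIONS: tuple[str, ...] = ("STN-L", "STN-R", "GPeA-L", "GPeA-R")


def channel_of(name: str) -> str:
    """Return 'left', 'right' or 'shared' for a population instance."""
    if name.endswith("-L"):
        return "left"
    if name.endswith("-R"):
        return "right"
    return "shared"


def base_type(name: str) -> str:
    """Strip the channel suffix: 'GPeP-L' -> 'GPeP'."""
    return name[:-2] if name.endswith(("-L", "-R")) else name


def swap_channels(name: str) -> str:
    """Mirror a population instance across channels (shared ones map to
    themselves)."""
    if name.endswith("-L"):
        return name[:-2] + "-R"
    if name.endswith("-R"):
        return name[:-2] + "-L"
    return name


# Cell-type level sign table: (source, target) -> +1 (excitatory) or -1
# (inhibitory).  Edges are expanded by channel in `connectivity_matrix`.
SIGN_TABLE: dict[tuple[str, str], int] = {
    # cortex
    ("Cx", "dSPN"): +1,
    ("Cx", "iSPN"): +1,
    ("Cx", "FSI"): +1,
    ("Cx", "STN"): +1,   # hyperdirect
    ("Cx", "CxI"): +1,
    ("CxI", "Cx"): -1,
    # striatal interneurons
    ("FSI", "dSPN"): -1,
    ("FSI", "iSPN"): -1,
    # direct pathway
    ("dSPN", "GPi"): -1,
    # indirect pathway
    ("iSPN", "GPeP"): -1,
    ("GPeP", "STN"): -1,
    ("GPeP", "GPi"): -1,
    ("GPeP", "GPeA"): -1,
    ("STN", "GPeP"): +1,
    ("STN", "GPi"): +1,
    # pallidostriatal pathway
    ("STN", "GPeA"): +1,
    ("GPeA", "dSPN"): -1,
    ("GPeA", "iSPN"): -1,
    ("GPeA", "FSI"): -1,
    # output and thalamocortical return
    ("GPi", "Th"): -1,
    ("Th", "Cx"): +1,
    ("Th", "dSPN"): +1,
    ("Th", "iSPN"): +1,
}


@dataclass(frozen=True)
class PopulationId:
    """A population instance: cell-type name plus action channel."""

    name: str

    def __post_init__(self) -> None:
        if self.name not in ALL_POPULATIONS:
            raise ValueError(f"unknown population {self.name!r}")

    @property
    def channel(self) -> str:
        return channel_of(self.name)

    @property
    def base(self) -> str:
        return base_type(self.name)


def expand_edges(weights: dict[tuple[str, str], float]) -> dict[tuple[str, str], float]:
    """Expand cell-type level signed weights into instance-level edges.

    ``weights`` maps cell-type pairs to non-negative magnitudes; the sign is
    taken from SIGN_TABLE.  Returns a map from (source instance, target
    instance) to signed weight.
    """
    edges: dict[tuple[str, str], float] = {}
    for (src, dst), mag in weights.items():
        if (src, dst) not in SIGN_TABLE:
            raise ValueError(f"connection {src}->{dst} not in the sign table")
        if mag < 0:
            raise ValueError(f"weight magnitude for {src}->{dst} must be >= 0")
        w = SIGN_TABLE[(src, dst)] * mag
        srcs = [src + "-L", src + "-R"] if src in LATERALIZED else [src]
        for s in srcs:
            if dst in LATERALIZED:
                if src in LATERALIZED:
                    # within-channel connection
                    d = dst + s[-2:]
                    edges[(s, d)] = w
                else:
                    # shared -> both channels
                    edges[(s, dst + "-L")] = w
                    edges[(s, dst + "-R")] = w
            else:
                # -> shared population
                edges[(s, dst)] = w
    return edges
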