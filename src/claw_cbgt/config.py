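"""Network configuration: weights, drives, noise, trial protocol.

A :class:`NetworkConfig` fully determines one stochastic rate network.  The
13 ``searchable_weights`` are the connection magnitudes explored by the
genetic search and jittered across networks in a pipeline run; they span
the direct, indirect and pallidostriatal pathways.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field, asdict

import numpy as np
import yaml

from .populations import (
    ALL_POPULATIONS,
    LATERALIZED,
    SHARED,
    SIGN_TABLE,
    POP_INDEX,
    expand_edges,
)

#: The 13 connection magnitudes subject to search/jitter, as cell-type pairs.
SEARCHABLE_WEIGHTS: tuple[tuple[str, str], ...] = (
    ("Cx", "dSPN"),
    ("Cx", "iSPN"),
    ("Cx", "STN"),
    ("dSPN", "GPi"),
    ("iSPN", "GPeP"),
    ("GPeP", "STN"),
    ("STN", "GPeP"),
    ("GPeP", "GPi"),
    ("STN", "GPi"),
    ("GPi", "Th"),
    ("GPeA", "dSPN"),
    ("GPeA", "iSPN"),
    ("STN", "GPeA"),
)


def _per_population(value_by_base: dict[str, float]) -> dict[str, float]:
    """Expand a per-cell-type map to the 18 population instances."""
    out: dict[str, float] = {}
    for base, v in value_by_base.items():
        if base in LATERALIZED:
            out[base + "-L"] = v
            out[base + "-R"] = v
        elif base in SHARED:
            out[base] = v
        else:
            raise ValueError(f"unknown cell type {base!r}")
    return out


@dataclass
class StimulusSpec:
    """Cortical stimulus: step input to Cx in each channel from onset until
    the decision; a configurable fraction is sustained to the selected
    channel during the consolidation phase."""

    onset_ms: float = 200.0
    amplitude_left: float = 20.0
    amplitude_right: float = 20.0
    consolidation_fraction: float = 0.5


@dataclass
class NetworkConfig:
    """All parameters of one stochastic CBGT rate network.

    weights map cell-type pairs to non-negative magnitudes; signs come from
    the fixed connectivity sign table.  Rates are in Hz, times in ms.
    """

    weights: dict = field(default_factory=dict)
    baseline_inputs: dict = field(default_factory=dict)
    noise_sd: dict = field(default_factory=dict)
    time_constants: dict = field(default_factory=dict)
    stimulus: StimulusSpec = field(default_factory=StimulusSpec)
    decision_threshold: float = 30.0
    timeout_ms: float = 1000.0
    dt_sim: float = 1.0
    bin_ms: float = 10.0
    consolidation_ms: float = 200.0
    intertrial_ms: float = 150.0
    rate_max: float = 150.0
    seed: int = 0

    # ------------------------------------------------------------------ #

    def validate(self) -> None:
        """Check signs, coverage and positivity; raise ValueError on failure."""
        if self.decision_threshold <= 0:
            raise ValueError("decision_threshold must be > 0")
        if self.timeout_ms <= 0:
            raise ValueError("timeout must be > 0")
        if self.dt_sim <= 0 or self.bin_ms <= 0:
            raise ValueError("dt_sim and bin_ms must be > 0")
        if self.bin_ms % self.dt_sim != 0:
            raise ValueError("bin_ms must be a multiple of dt_sim")
        for pair in self.weights:
            if tuple(pair) not in SIGN_TABLE:
                raise ValueError(f"connection {pair} not in the sign table")
            if self.weights[pair] < 0:
                raise ValueError(f"weight magnitude {pair} must be >= 0")
        for pair in SEARCHABLE_WEIGHTS:
            if pair not in self.weights:
                raise ValueError(f"searchable weight {pair} missing")
        for name in ALL_POPULATIONS:
            for table, label in (
                (self.baseline_inputs, "baseline_inputs"),
                (self.noise_sd, "noise_sd"),
                (self.time_constants, "time_constants"),
            ):
                if name not in table:
                    raise ValueError(f"{label} missing population {name}")
        if any(tau <= 0 for tau in self.time_constants.values()):
            raise ValueError("time constants must be > 0")

    # ------------------------------------------------------------------ #

    def weight_matrix(self) -> np.ndarray:
        """Signed 18x18 connection matrix W with W[i, j] the weight from
        population j onto population i."""
        W = np.zeros((len(ALL_POPULATIONS), len(ALL_POPULATIONS)))
        for (src, dst), w in expand_edges(self.weights).items():
            W[POP_INDEX[dst], POP_INDEX[src]] = w
        return W

    def vectors(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """(baseline input, noise sd, time constants) as aligned arrays."""
        I = np.array([self.baseline_inputs[p] for p in ALL_POPULATIONS])
        sd = np.array([self.noise_sd[p] for p in ALL_POPULATIONS])
        tau = np.array([self.time_constants[p] for p in ALL_POPULATIONS])
        return I, sd, tau

    def copy(self) -> "NetworkConfig":
        return copy.deepcopy(self)

    def with_searchable(self, values: dict[tuple[str, str], float]) -> "NetworkConfig":
        """Return a copy with some searchable weight magnitudes replaced."""
        cfg = self.copy()
        for pair, v in values.items():
            if tuple(pair) not in SEARCHABLE_WEIGHTS:
                raise ValueError(f"{pair} is not a searchable weight")
            cfg.weights[tuple(pair)] = float(v)
        return cfg

    # ------------------------------------------------------------------ #

    def to_dict(self) -> dict:
        d = asdict(self)
        d["weights"] = {f"{s}->{t}": v for (s, t), v in self.weights.items()}
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "NetworkConfig":
        d = copy.deepcopy(d)
        d["weights"] = {
            tuple(k.split("->")): v for k, v in d.get("weights", {}).items()
        }
        stim = d.get("stimulus", {})
        if isinstance(stim, dict):
            d["stimulus"] = StimulusSpec(**stim)
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "NetworkConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------- #
# Shipped default configuration.
#
# Tuned so that, qualitatively: GPeP and GPi sit at a high baseline and dip
# under drive; dSPN, iSPN and GPeA sit low and surge after stimulus onset;
# thalamus ramps from a low baseline through 30 Hz; fewer than 1% of trials
# time out at 1000 ms; and cortical and striatal activity are positively
# correlated across trials.
# ---------------------------------------------------------------------- #

DEFAULT_WEIGHTS: dict[tuple[str, str], float] = {
    ("Cx", "dSPN"): 0.75,
    ("Cx", "iSPN"): 0.65,
    ("Cx", "FSI"): 0.20,
    ("Cx", "STN"): 0.25,
    ("Cx", "CxI"): 0.40,
    ("CxI", "Cx"): 0.60,
    ("FSI", "dSPN"): 0.30,
    ("FSI", "iSPN"): 0.30,
    ("dSPN", "GPi"): 1.50,
    ("iSPN", "GPeP"): 1.30,
    ("GPeP", "STN"): 0.35,
    ("GPeP", "GPi"): 0.25,
    ("GPeP", "GPeA"): 0.45,
    ("STN", "GPeP"): 0.30,
    ("STN", "GPi"): 0.50,
    ("STN", "GPeA"): 0.40,
    ("GPeA", "dSPN"): 0.30,
    ("GPeA", "iSPN"): 0.30,
    ("GPeA", "FSI"): 0.20,
    ("GPi", "Th"): 1.00,
    ("Th", "Cx"): 0.70,
    ("Th", "dSPN"): 0.12,
    ("Th", "iSPN"): 0.10,
}

DEFAULT_BASELINES = _per_population(
    {
        "Cx": 14.0,
        "CxI": 2.0,
        "FSI": 8.0,
        "dSPN": 2.0,
        "iSPN": 2.0,
        "GPeP": 78.0,
        "GPeA": 28.0,
        "STN": 22.0,
        "GPi": 70.0,
        "Th": 52.0,
    }
)

DEFAULT_NOISE_SD = _per_population(
    {
        "Cx": 1.2,
        "CxI": 0.6,
        "FSI": 0.6,
        "dSPN": 0.9,
        "iSPN": 0.9,
        "GPeP": 1.2,
        "GPeA": 0.8,
        "STN": 1.0,
        "GPi": 1.2,
        "Th": 1.0,
    }
)

DEFAULT_TAU = _per_population(
    {
        "Cx": 20.0,
        "CxI": 10.0,
        "FSI": 10.0,
        "dSPN": 20.0,
        "iSPN": 20.0,
        "GPeP": 15.0,
        "GPeA": 15.0,
        "STN": 10.0,
        "GPi": 15.0,
        "Th": 20.0,
    }
)


def default_config(seed: int = 0) -> NetworkConfig:
    """The shipped default network configuration."""
    cfg = NetworkConfig(
        weights=dict(DEFAULT_WEIGHTS),
        baseline_inputs=dict(DEFAULT_BASELINES),
        noise_sd=dict(DEFAULT_NOISE_SD),
        time_constants=dict(DEFAULT_TAU),
        seed=seed,
    )
    cfg.validate()
    return cfg


#: Default per-cell-type target mean firing-rate ranges (Hz) used by the
#: genetic search feasibility filter.  Wide bands around the regimes the
#: default network is tuned to occupy.
DEFAULT_RATE_TARGETS: dict[str, tuple[float, float]] = {
    "Cx": (5.0, 40.0),
    "CxI": (1.0, 40.0),
    "FSI": (2.0, 40.0),
    "dSPN": (0.0, 30.0),
    "iSPN": (0.0, 30.0),
    "GPeP": (30.0, 110.0),
    "GPeA": (0.0, 35.0),
    "STN": (5.0, 60.0),
    "GPi": (25.0, 100.0),
    "Th": (2.0, 40.0),
}
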