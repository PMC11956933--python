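"""Stochastic population-rate simulation of two-choice CBGT trials.

Each population's rate follows a noisy leaky update

    r_i(t+dt) = r_i + dt/tau_i * (-r_i + phi(sum_j W_ij r_j + I_i + stim_i))
                + sd_i * sqrt(dt) * xi,

with ``phi`` a non-negative saturating transfer function, rates clipped at
zero, and all times in ms.  A trial runs through a pre-stimulus phase, a
decision phase that ends when a thalamic population's binned rate first
reaches the decision threshold (30 Hz by default) or times out at 1000 ms,
then a consolidation phase with partial cortical input to the selected
channel, and an inter-trial interval.  Rates are reported as bin means on a
10 ms grid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .config import NetworkConfig
from .populations import ALL_POPULATIONS, POP_INDEX

#: Marker used for `decision_time` on trials that timed out.
TIMEOUT = float("inf")


class IntegrationError(RuntimeError):
    """Raised when the rate integration produces non-finite values."""


@dataclass
class TrialRecord:
    """One simulated trial: binned rates plus the behavioral outcome.

    rates has shape (18, n_bins) in Hz on the `bin_ms` grid, covering all
    phases of the trial.  decision_time is in ms from stimulus onset, or
    the TIMEOUT marker; choice is 'left', 'right' or 'none'.  phase_marks
    gives bin indices: stimulus onset, first post-decision bin, end of
    consolidation.
    """

    rates: np.ndarray
    decision_time: float
    choice: str
    phase_marks: dict = field(default_factory=dict)
    bin_ms: float = 10.0
    trial_id: int = 0

    @property
    def timed_out(self) -> bool:
        return not np.isfinite(self.decision_time)

    @property
    def n_bins(self) -> int:
        return self.rates.shape[1]

    @property
    def decision_bin(self) -> int:
        """Index of the last bin of the decision phase (the bin in which
        threshold was reached, or the last pre-timeout bin)."""
        return self.phase_marks["decision_end"]

    @property
    def stim_onset_bin(self) -> int:
        return self.phase_marks["stim_onset"]

    def decision_rates(self) -> np.ndarray:
        """Rates truncated at decision time (pre-stimulus bins included)."""
        return self.rates[:, : self.decision_bin + 1]


@dataclass
class RateTraceSet:
    """A collection of simulated networks, each a (config, trials) pair."""

    networks: list = field(default_factory=list)
    n_trials_per_network: int = 50

    def add(self, config: NetworkConfig, trials: list) -> None:
        self.networks.append((config, trials))

    def __len__(self) -> int:
        return len(self.networks)

    def __iter__(self):
        return iter(self.networks)


def _transfer(x: np.ndarray, rate_max: float) -> np.ndarray:
    """Non-negative saturating transfer: linear near zero, saturates at
    rate_max."""
    return rate_max * np.tanh(np.maximum(x, 0.0) / rate_max)


def resting_state(config: NetworkConfig, t_settle_ms: float = 2000.0) -> np.ndarray:
    """Noise-free fixed point of the rate dynamics (deterministic settle)."""
    W = config.weight_matrix()
    I, _, tau = config.vectors()
    dt = config.dt_sim
    r = np.zeros(len(ALL_POPULATIONS))
    for _ in range(int(t_settle_ms / dt)):
        drive = W @ r + I
        r = r + dt / tau * (-r + _transfer(drive, config.rate_max))
        r = np.maximum(r, 0.0)
    return r


def simulate_trial(config: NetworkConfig, seed: int, r0: np.ndarray | None = None) -> TrialRecord:
    """Simulate one two-choice trial.

    Identical (config, seed) always yields an identical record.  ``r0``
    optionally supplies the initial rate vector (defaults to the noise-free
    resting state, computed once per call if not given).
    """
    config.validate()
    rng = np.random.default_rng(seed)
    W = config.weight_matrix()
    I, sd, tau = config.vectors()
    dt = config.dt_sim
    steps_per_bin = int(round(config.bin_ms / dt))
    sqrt_dt = np.sqrt(dt)
    rmax = config.rate_max

    stim = config.stimulus
    i_cxl, i_cxr = POP_INDEX["Cx-L"], POP_INDEX["Cx-R"]
    i_thl, i_thr = POP_INDEX["Th-L"], POP_INDEX["Th-R"]

    n_pre_bins = int(round(stim.onset_ms / config.bin_ms))
    max_decision_bins = int(round(config.timeout_ms / config.bin_ms))
    n_cons_bins = int(round(config.consolidation_ms / config.bin_ms))
    n_iti_bins = int(round(config.intertrial_ms / config.bin_ms))

    r = np.array(r0 if r0 is not None else resting_state(config), dtype=float)
    bins: list[np.ndarray] = []

    def step(stim_vec: np.ndarray) -> None:
        nonlocal r
        drive = W @ r + I + stim_vec
        noise = sd * sqrt_dt * rng.standard_normal(r.shape)
        r = r + dt / tau * (-r + _transfer(drive, rmax)) + noise
        r = np.maximum(r, 0.0)

    def run_bin(stim_vec: np.ndarray) -> np.ndarray:
        acc = np.zeros_like(r)
        for _ in range(steps_per_bin):
            step(stim_vec)
            acc += r
        mean = acc / steps_per_bin
        if not np.all(np.isfinite(mean)):
            bad = int(np.argmax(~np.isfinite(mean)))
            raise IntegrationError(
                f"non-finite rate in population {ALL_POPULATIONS[bad]} "
                f"at bin {len(bins)}"
            )
        bins.append(mean)
        return mean

    zero_stim = np.zeros_like(r)
    for _ in range(n_pre_bins):
        run_bin(zero_stim)

    stim_vec = np.zeros_like(r)
    stim_vec[i_cxl] = stim.amplitude_left
    stim_vec[i_cxr] = stim.amplitude_right

    decision_time = TIMEOUT
    choice = "none"
    decision_end = n_pre_bins + max_decision_bins - 1
    for b in range(max_decision_bins):
        mean = run_bin(stim_vec)
        if mean[i_thl] >= config.decision_threshold or mean[i_thr] >= config.decision_threshold:
            decision_time = (b + 1) * config.bin_ms
            choice = "left" if mean[i_thl] >= mean[i_thr] else "right"
            decision_end = n_pre_bins + b
            break

    cons_vec = np.zeros_like(r)
    if choice == "left":
        cons_vec[i_cxl] = stim.amplitude_left * stim.consolidation_fraction
    elif choice == "right":
        cons_vec[i_cxr] = stim.amplitude_right * stim.consolidation_fraction
    for _ in range(n_cons_bins):
        run_bin(cons_vec)
    for _ in range(n_iti_bins):
        run_bin(zero_stim)

    rates = np.column_stack(bins)
    marks = {
        "stim_onset": n_pre_bins,
        "decision_end": decision_end,
        "consolidation_end": decision_end + 1 + n_cons_bins,
    }
    return TrialRecord(
        rates=rates,
        decision_time=decision_time,
        choice=choice,
        phase_marks=marks,
        bin_ms=config.bin_ms,
    )


def trial_seeds(seed: int, n_trials: int) -> list[int]:
    """Deterministic per-trial sub-seeds (below 2**31) derived from seed."""
    ss = np.random.SeedSequence(seed)
    return [int(s) % (2**31) for s in ss.generate_state(n_trials)]


def run_experiment(config: NetworkConfig, n_trials: int, seed: int) -> tuple[NetworkConfig, list]:
    """Simulate ``n_trials`` independent trials of one network.

    Per-trial sub-seeds derive deterministically from ``seed``; the
    noise-free resting state is computed once and shared as the initial
    condition of every trial.
    """
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    r0 = resting_state(config)
    trials = []
    for i, s in enumerate(trial_seeds(seed, n_trials)):
        try:
            rec = simulate_trial(config, s, r0=r0)
        except IntegrationError as err:
            raise IntegrationError(f"trial {i}: {err}") from err
        rec.trial_id = i
        trials.append(rec)
    return config, trials


def timeout_fraction(trials: list) -> float:
    return sum(t.timed_out for t in trials) / len(trials)


def cortex_striatum_correlation(trials: list) -> float:
    """Correlation, across non-timeout trials, of trial-mean cortical rate
    versus trial-mean striatal (dSPN + iSPN) rate over the decision phase."""
    cx, st = [], []
    idx_cx = [POP_INDEX["Cx-L"], POP_INDEX["Cx-R"]]
    idx_st = [POP_INDEX[p] for p in ("dSPN-L", "dSPN-R", "iSPN-L", "iSPN-R")]
    for t in trials:
        if t.timed_out:
            continue
        seg = t.decision_rates()
        cx.append(seg[idx_cx].mean())
        st.append(seg[idx_st].mean())
    if len(cx) < 3:
        return float("nan")
    c = np.corrcoef(cx, st)[0, 1]
    return float(c)
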