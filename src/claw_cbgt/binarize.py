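"""Histogram-based binarization of binned firing rates.

Per population, rates from all trials up to each trial's decision time are
pooled into a histogram.  For unimodal histograms the threshold is placed
at the 10% cumulative-count rate when the baseline (pre-stimulus) rate
exceeds the rate near decision times — appropriate for populations such as
GPeP and GPi that sit high and dip under drive — and at the 90%
cumulative-count rate otherwise (populations that sit low and surge, such
as dSPN, iSPN and GPeA).  For bimodal histograms the threshold is the
midpoint between the two detected peaks.  A bin's bit is 1 iff its rate is
strictly above the threshold.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import find_peaks

from .populations import ALL_POPULATIONS, POP_INDEX
from .simulate import TrialRecord


@dataclass
class RateHistogram:
    """Pooled firing-rate histogram of one population (trials up to DT)."""

    population: str
    bin_edges: np.ndarray
    counts: np.ndarray
    modality: str          # 'unimodal' | 'bimodal'
    baseline_rate: float   # mean over pre-stimulus bins
    near_dt_rate: float    # mean over the last k bins before decision
    peak_rates: tuple = ()  # detected peak locations (Hz)

    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class ThresholdEntry:
    population: str
    threshold: float
    rule_applied: str      # 'low10' | 'high90' | 'bimodal_midpoint'


@dataclass
class BinarizationThresholds:
    entries: dict = field(default_factory=dict)

    def threshold(self, population: str) -> float:
        return self.entries[population].threshold

    def __contains__(self, population: str) -> bool:
        return population in self.entries

    def to_records(self) -> list[dict]:
        return [
            {"population": e.population, "threshold_hz": e.threshold,
             "rule": e.rule_applied}
            for e in self.entries.values()
        ]


@dataclass
class BinaryTrial:
    """Boolean matrix (18 populations x bins up to decision time) of one
    trial, with the behavioral outcome carried along."""

    bits: np.ndarray
    choice: str
    decision_time: float
    trial_id: int = 0


@dataclass
class BinaryTraceSet:
    trials: list = field(default_factory=list)


def _histogram_bins(samples: np.ndarray) -> np.ndarray:
    """Freedman-Diaconis bin edges with a 1 Hz minimum width."""
    q75, q25 = np.percentile(samples, [75, 25])
    iqr = q75 - q25
    width = 2 * iqr / len(samples) ** (1 / 3) if iqr > 0 else 0.0
    width = max(width, 1.0)
    lo, hi = samples.min(), samples.max()
    n = max(int(np.ceil((hi - lo) / width)), 1)
    return np.linspace(lo, lo + n * width, n + 1)


def _detect_modality(counts: np.ndarray, edges: np.ndarray,
                     smooth_width: int = 5,
                     prominence_frac: float = 0.10) -> tuple[str, tuple]:
    """Classify a histogram as unimodal or bimodal.

    Counts are smoothed with a moving average and local maxima with
    prominence at least ``prominence_frac`` of the global maximum are
    counted; exactly two maxima means bimodal.
    """
    if len(counts) < 3:
        return "unimodal", ()
    kernel = np.ones(smooth_width) / smooth_width
    smooth = np.convolve(counts.astype(float), kernel, mode="same")
    prom = prominence_frac * smooth.max()
    # pad so peaks at the boundary are found
    padded = np.concatenate([[0.0], smooth, [0.0]])
    peaks, _ = find_peaks(padded, prominence=prom)
    centers = (edges[:-1] + edges[1:]) / 2
    locs = tuple(float(centers[p - 1]) for p in peaks)
    if len(locs) == 2:
        return "bimodal", locs
    return "unimodal", locs


def build_histograms(trials: list, k_near: int = 3) -> list[RateHistogram]:
    """One pooled histogram per population over all non-timeout trials,
    using bins up to each trial's decision time.

    ``k_near`` sets how many bins before the decision define the
    near-decision rate.
    """
    ok = [t for t in trials if isinstance(t, TrialRecord) and not t.timed_out]
    if not ok:
        raise ValueError("all trials timed out; no histograms can be built")
    out = []
    for name in ALL_POPULATIONS:
        i = POP_INDEX[name]
        pooled = np.concatenate([t.decision_rates()[i] for t in ok])
        base = np.concatenate([t.rates[i, : t.stim_onset_bin] for t in ok])
        near = np.concatenate(
            [t.decision_rates()[i][-k_near:] for t in ok]
        )
        edges = _histogram_bins(pooled)
        counts, _ = np.histogram(pooled, bins=edges)
        modality, locs = _detect_modality(counts, edges)
        out.append(
            RateHistogram(
                population=name,
                bin_edges=edges,
                counts=counts,
                modality=modality,
                baseline_rate=float(base.mean()) if base.size else float(pooled.mean()),
                near_dt_rate=float(near.mean()),
                peak_rates=locs,
            )
        )
    return out


def select_threshold(hist: RateHistogram) -> ThresholdEntry:
    """Apply the threshold-selection rule to one histogram."""
    total = hist.total()
    if total <= 0:
        raise ValueError(f"empty histogram for {hist.population}")
    centers = (hist.bin_edges[:-1] + hist.bin_edges[1:]) / 2
    if len(centers) == 1 or hist.bin_edges[-1] - hist.bin_edges[0] <= 1.0 + 1e-12:
        # single distinct value (degenerate)
        warnings.warn(
            f"degenerate histogram for {hist.population}; threshold set at "
            f"the single observed rate"
        )
        return ThresholdEntry(hist.population, float(centers[len(centers) // 2]),
                              "high90" if hist.baseline_rate <= hist.near_dt_rate else "low10")
    if hist.modality == "bimodal" and len(hist.peak_rates) == 2:
        thr = float(np.mean(hist.peak_rates))
        return ThresholdEntry(hist.population, thr, "bimodal_midpoint")
    cum = np.cumsum(hist.counts)
    if hist.baseline_rate > hist.near_dt_rate:
        frac, rule = 0.10, "low10"
    else:
        frac, rule = 0.90, "high90"
    idx = int(np.searchsorted(cum, frac * total))
    idx = min(idx, len(centers) - 1)
    return ThresholdEntry(hist.population, float(centers[idx]), rule)


def select_thresholds(hists: list) -> BinarizationThresholds:
    th = BinarizationThresholds()
    for h in hists:
        th.entries[h.population] = select_threshold(h)
    return th


def binarize_traces(trials: list, thresholds: BinarizationThresholds) -> BinaryTraceSet:
    """Binarize each non-timeout trial's rates (strictly above threshold ->
    1), truncated at decision time."""
    thr = np.empty(len(ALL_POPULATIONS))
    for name in ALL_POPULATIONS:
        if name not in thresholds:
            raise ValueError(f"missing threshold for population {name}")
        thr[POP_INDEX[name]] = thresholds.threshold(name)
    out = BinaryTraceSet()
    for t in trials:
        if t.timed_out:
            continue
        bits = t.decision_rates() > thr[:, None]
        out.trials.append(
            BinaryTrial(bits=bits, choice=t.choice,
                        decision_time=t.decision_time, trial_id=t.trial_id)
        )
    return out


def binarize_network(trials: list, k_near: int = 3) -> tuple[BinaryTraceSet, BinarizationThresholds]:
    """Convenience: estimate thresholds from one network's trials and
    binarize them."""
    hists = build_histograms(trials, k_near=k_near)
    thresholds = select_thresholds(hists)
    return binarize_traces(trials, thresholds), thresholds
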