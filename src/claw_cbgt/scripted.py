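"""Scripted-trace generator: rate traces that binarize to a prescribed
state walk, used as exact fixtures for the downstream graph machinery."""

from __future__ import annotations

import numpy as np

from .populations import ALL_POPULATIONS, ENCODED_POPULATIONS, POP_INDEX
from .simulate import TrialRecord


def generate_scripted_traces(script: list, thresholds: dict,
                             margin: float = 5.0, bin_ms: float = 10.0) -> TrialRecord:
    """Emit a TrialRecord whose binarization recovers ``script`` exactly.

    ``script`` is a list of (pattern, dwell_bins) pairs, where a pattern is
    a Boolean 10-vector over the encoded populations (or a set of active
    population names); ``thresholds`` maps population names to binarization
    thresholds in Hz.  Active bits sit a margin above the threshold,
    inactive bits a margin below (floored at 0); thalamic rates stay below
    the 30 Hz decision threshold except in the final pattern, which must
    contain an active thalamic bit so the trial closes with a decision.
    """
    if not script:
        raise ValueError("script must contain at least one pattern")
    patterns = []
    for pat, dwell in script:
        if dwell < 1:
            raise ValueError("dwell bins must be >= 1")
        if isinstance(pat, (set, frozenset, list, tuple)) and all(
            isinstance(x, str) for x in pat
        ):
            vec = np.array([p in set(pat) for p in ENCODED_POPULATIONS])
        else:
            vec = np.asarray(pat, dtype=bool)
            if vec.shape != (len(ENCODED_POPULATIONS),):
                raise ValueError("pattern must cover the 10 encoded populations")
        patterns.append((vec, int(dwell)))

    final = patterns[-1][0]
    th_bits = [ENCODED_POPULATIONS.index("Th-L"), ENCODED_POPULATIONS.index("Th-R")]
    if not any(final[b] for b in th_bits):
        raise ValueError("final pattern must activate a thalamic population")

    n_bins = sum(d for _, d in patterns)
    rates = np.zeros((len(ALL_POPULATIONS), n_bins))
    # non-encoded populations: constant nominal rate
    for name in ALL_POPULATIONS:
        if name not in ENCODED_POPULATIONS:
            rates[POP_INDEX[name], :] = 10.0

    col = 0
    for k, (vec, dwell) in enumerate(patterns):
        is_final = k == len(patterns) - 1
        for name, bit in zip(ENCODED_POPULATIONS, vec):
            thr = float(thresholds[name])
            if bit:
                hi = thr + margin
                if name.startswith("Th"):
                    # stay below the decision threshold until the end
                    hi = max(thr + min(margin, (30.0 - thr) / 2), thr + 0.5)
                    if is_final:
                        hi = max(thr + margin, 35.0)
                rates[POP_INDEX[name], col:col + dwell] = hi
            else:
                rates[POP_INDEX[name], col:col + dwell] = max(thr - margin, 0.0)
        col += dwell

    i_thl, i_thr = POP_INDEX["Th-L"], POP_INDEX["Th-R"]
    choice = "left" if rates[i_thl, -1] >= rates[i_thr, -1] else "right"
    return TrialRecord(
        rates=rates,
        decision_time=n_bins * bin_ms,
        choice=choice,
        phase_marks={"stim_onset": 0, "decision_end": n_bins - 1,
                     "consolidation_end": n_bins - 1},
        bin_ms=bin_ms,
    )
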