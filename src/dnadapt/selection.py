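"""Electrode screening: visual responsiveness and category selectivity.

An electrode counts as visually responsive when (i) its average
duration-trial response has a signal-to-noise z-score mean/SD over time
above threshold (0.2 by default) and (ii) a response onset latency can
be determined: the z-scored time course must exceed 0.85 within ~300 ms
of stimulus onset and stay above it for at least ~120 ms (150 and 60
samples at 512 Hz; specified in seconds so other rates rescale).

Category selectivity is scored with d', the standardized difference
between the response to one category and the pooled response to the
other categories (scrambled excluded from both the candidate set and
the comparison pool):

    d' = (mean_cat - mean_other) / sqrt((sd_cat^2 + sd_other^2) / 2)

where means and SDs are taken over time samples of the average
duration-trial responses.  An electrode is called selective at
threshold theta if its best d' exceeds theta and the across-category
average response has a measurable onset.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .trial_design import CATEGORIES, round_half_away

__all__ = [
    "ResponsivenessResult", "SelectivityResult",
    "electrode_zscore", "onset_latency", "dprime", "classify_selectivity",
    "responsiveness", "DPRIME_THRESHOLDS",
]

DPRIME_THRESHOLDS = (0.5, 0.75, 1.0)
#: Onset search window and required supra-threshold run, in seconds
#: (150 and 60 samples at 512 Hz).
ONSET_SEARCH_S = 150 / 512
ONSET_RUN_S = 60 / 512
ONSET_Z_THRESHOLD = 0.85
ZSCORE_THRESHOLD = 0.2


@dataclass
class ResponsivenessResult:
    electrode_id: str
    zscore: float
    onset_latency_s: Optional[float]
    included: bool


@dataclass
class SelectivityResult:
    dprime: dict[str, float]          # per candidate category
    preferred: str
    selective_at: dict[float, bool]
    onset_latency_s: Optional[float]


def electrode_zscore(tc: np.ndarray) -> float:
    """Signal-to-noise over time: mean(tc) / sd(tc)."""
    tc = np.asarray(tc, dtype=float)
    if tc.size < 2:
        raise ValueError("time course must have at least 2 samples")
    sd = tc.std()
    if sd == 0:
        raise ValueError("constant time course; z-score undefined")
    return float(tc.mean() / sd)


def onset_latency(tc: np.ndarray, fs: float, onset_index: int = 0,
                  search_s: float = ONSET_SEARCH_S,
                  run_s: float = ONSET_RUN_S,
                  z_threshold: float = ONSET_Z_THRESHOLD
                  ) -> Optional[float]:
    """First post-onset time at which the z-scored response exceeds the
    threshold and stays above it for the required run; None if absent."""
    tc = np.asarray(tc, dtype=float)
    sd = tc.std()
    if sd == 0:
        return None
    z = (tc - tc.mean()) / sd
    search = round_half_away(search_s * fs)
    run = round_half_away(run_s * fs)
    above = z > z_threshold
    stop = min(onset_index + search, tc.size)
    for i in range(onset_index, stop):
        if i + run <= tc.size and above[i:i + run].all():
            return float((i - onset_index) / fs)
    return None


def dprime(mean_cat: float, sd_cat: float, mean_other: float,
           sd_other: float) -> float:
    """Standardized category contrast with pooled variance denominator."""
    if sd_cat < 0 or sd_other < 0:
        raise ValueError("standard deviations must be >= 0")
    denom = np.sqrt((sd_cat ** 2 + sd_other ** 2) / 2.0)
    if denom == 0:
        raise ValueError("both standard deviations are zero; d' undefined")
    return float((mean_cat - mean_other) / denom)


def classify_selectivity(responses: Mapping[str, np.ndarray], fs: float,
                         onset_index: int = 0,
                         thresholds: Sequence[float] = DPRIME_THRESHOLDS
                         ) -> SelectivityResult:
    """Score category selectivity from per-category average duration
    responses.

    For each candidate category (scrambled excluded) the "other" pool
    concatenates the time samples of the remaining categories (again
    excluding scrambled).  Selectivity additionally requires an onset
    latency on the across-category average response.
    """
    missing = set(CATEGORIES) - set(responses)
    if missing:
        raise ValueError(f"missing categories: {sorted(missing)}")
    tcs = {c: np.asarray(responses[c], dtype=float) for c in CATEGORIES}
    candidates = [c for c in CATEGORIES if c != "scrambled"]
    d: dict[str, float] = {}
    for cat in candidates:
        others = np.concatenate([tcs[c] for c in candidates if c != cat])
        d[cat] = dprime(tcs[cat].mean(), tcs[cat].std(),
                        others.mean(), others.std())
    preferred = max(d, key=d.get)
    overall = np.mean([tcs[c] for c in CATEGORIES], axis=0)
    onset = onset_latency(overall, fs, onset_index)
    best = d[preferred]
    flags = {float(th): bool(best > th and onset is not None)
             for th in thresholds}
    return SelectivityResult(dprime=d, preferred=preferred,
                             selective_at=flags, onset_latency_s=onset)


def responsiveness(tc: np.ndarray, fs: float, onset_index: int = 0,
                   z_threshold: float = ZSCORE_THRESHOLD,
                   electrode_id: str = "e0") -> ResponsivenessResult:
    """Visual-responsiveness screen on the average duration response."""
    z = electrode_zscore(tc)
    onset = onset_latency(tc, fs, onset_index)
    return ResponsivenessResult(electrode_id=electrode_id, zscore=z,
                                onset_latency_s=onset,
                                included=bool(onset is not None
                                              and z > z_threshold))
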