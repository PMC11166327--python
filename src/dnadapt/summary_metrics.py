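"""Shape and adaptation metrics computed from response time courses.

Metrics follow the conventions used for broadband iEEG adaptation
analyses:

* **time-to-peak** -- stimulus onset to response maximum (computed on the
  longest, 533 ms, duration condition by convention);
* **FWHM** -- time between the first rise above and the last decay below
  half of the maximum, with sub-sample linear interpolation;
* **recovery from adaptation** -- for each repetition (ISI) condition the
  response to the second stimulus is isolated by subtracting a
  first-response template (the average of the 134 ms duration response
  and each repetition response up to its second-stimulus onset), and the
  recovery ratio is AUC(second) / AUC(first);
* **overall adaptation** -- the recovery ratio averaged over all ISIs;
* **long-term recovery** -- the intercept ``c`` of the log-linear fit
  ``recovery = c + a * ln(ISI)``, i.e. the predicted recovery at a 1 s
  ISI.

AUCs are trapezoidal, taken from the (first or second) stimulus onset to
the end of the epoch, with negative samples of the subtraction-derived
estimate clipped to zero before integration; both choices are
configurable.  Metrics operate on unsmoothed averages.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np

from .trial_design import (MONITOR_HZ, REPETITION_DURATION_FRAMES,
                           canonical_isis, round_half_away)

__all__ = [
    "SecondResponseEstimate", "RecoveryCurve",
    "time_to_peak", "fwhm", "estimate_second_response", "recovery_ratio",
    "overall_adaptation", "fit_recovery_curve", "compute_recovery_curve",
]


@dataclass
class SecondResponseEstimate:
    """Isolated second-stimulus response for one repetition condition."""

    fs: float
    first_response: np.ndarray    # first-response template, full epoch
    second_response: np.ndarray   # zero before the second-stimulus onset
    isi_s: float
    onset_index: int
    second_onset_index: int


@dataclass
class RecoveryCurve:
    isi_s: np.ndarray
    recovery: np.ndarray
    c: Optional[float] = None     # long-term recovery (value at 1 s ISI)
    a: Optional[float] = None     # natural-log slope

    def __post_init__(self) -> None:
        self.isi_s = np.asarray(self.isi_s, dtype=float)
        self.recovery = np.asarray(self.recovery, dtype=float)
        if np.any(np.diff(self.isi_s) <= 0):
            raise ValueError("ISIs must be strictly increasing")
        if np.any(self.recovery < 0):
            raise ValueError("recovery ratios must be >= 0")

    def to_dict(self) -> dict:
        return {"isi": self.isi_s.tolist(), "recovery": self.recovery.tolist(),
                "c": self.c, "a": self.a}


def time_to_peak(tc: np.ndarray, fs: float, onset_index: int = 0) -> float:
    """Seconds from stimulus onset to the maximum; earliest index on ties."""
    tc = np.asarray(tc, dtype=float)
    seg = tc[onset_index:]
    if seg.size == 0 or np.all(seg == seg[0]):
        raise ValueError("time course has no peak after onset")
    return float(np.argmax(seg) / fs)


def _cross_time(x0: float, x1: float, half: float) -> float:
    """Fractional offset in [0, 1] where the segment x0->x1 crosses half."""
    if x1 == x0:
        return 0.0
    return (half - x0) / (x1 - x0)


def fwhm(tc: np.ndarray, fs: float) -> float:
    """Full width at half maximum in seconds; NaN if the response never
    decays below half max within the window (undefined, flagged)."""
    tc = np.asarray(tc, dtype=float)
    m = tc.max()
    if m <= 0:
        raise ValueError("time course maximum must be positive")
    half = m / 2.0
    above = tc >= half
    first = int(np.argmax(above))
    last = int(len(tc) - 1 - np.argmax(above[::-1]))
    if last == len(tc) - 1:
        return float("nan")   # still above half max at the window's end
    if first == 0:
        t_up = 0.0
    else:
        t_up = (first - 1 + _cross_time(tc[first - 1], tc[first], half)) / fs
    t_down = (last + _cross_time(tc[last], tc[last + 1], half)) / fs
    return float(t_down - t_up)


def _second_onsets(fs: float, onset_index: int,
                   isis_s: Sequence[float]) -> list[int]:
    w = round_half_away(REPETITION_DURATION_FRAMES / MONITOR_HZ * fs)
    return [onset_index + w + round_half_away(float(isi) * fs)
            for isi in isis_s]


def estimate_second_response(rep_tcs: Mapping[int, np.ndarray],
                             dur134_tc: np.ndarray, fs: float,
                             onset_index: int,
                             isis_s: Optional[Sequence[float]] = None
                             ) -> dict[int, SecondResponseEstimate]:
    """Isolate second-stimulus responses for each repetition condition.

    The first-response template averages, at every time sample, the
    134 ms duration response with every repetition response whose
    second stimulus has not yet appeared; past all second onsets the
    template continues as the 134 ms response alone.  Each isolated
    second response is the repetition response minus the template,
    zeroed before that condition's second-stimulus onset.
    """
    if isis_s is None:
        isis_s = [float(x) for x in canonical_isis()]
    levels = sorted(rep_tcs)
    if len(levels) != len(isis_s):
        raise ValueError("one repetition time course per ISI is required")
    dur134_tc = np.asarray(dur134_tc, dtype=float)
    T = dur134_tc.size
    for lv in levels:
        if len(rep_tcs[lv]) != T:
            raise ValueError("misaligned time-course lengths")
    onsets2 = dict(zip(levels, _second_onsets(fs, onset_index, isis_s)))

    total = dur134_tc.copy()
    count = np.ones(T)
    for lv in levels:
        o2 = onsets2[lv]
        total[:o2] += np.asarray(rep_tcs[lv], dtype=float)[:o2]
        count[:o2] += 1
    template = total / count

    out: dict[int, SecondResponseEstimate] = {}
    for lv, isi in zip(levels, isis_s):
        o2 = onsets2[lv]
        second = np.asarray(rep_tcs[lv], dtype=float) - template
        second[:o2] = 0.0
        out[lv] = SecondResponseEstimate(fs, template, second, float(isi),
                                         onset_index, o2)
    return out


def recovery_ratio(est: SecondResponseEstimate, clip_negative: bool = True
                   ) -> float:
    """AUC(second response) / AUC(first response), onset to epoch end."""
    first = est.first_response[est.onset_index:]
    second = est.second_response[est.second_onset_index:]
    if clip_negative:
        first = np.clip(first, 0.0, None)
        second = np.clip(second, 0.0, None)
    auc_first = np.trapezoid(first) / est.fs
    if auc_first <= 0:
        raise ValueError("first-response AUC must be positive")
    return float((np.trapezoid(second) / est.fs) / auc_first)


def overall_adaptation(curve: RecoveryCurve) -> float:
    """Recovery ratio averaged over all ISIs."""
    return float(np.mean(curve.recovery))


def fit_recovery_curve(isi_s: Sequence[float], recovery: Sequence[float]
                       ) -> tuple[float, float]:
    """Least-squares fit of ``recovery = c + a * ln(isi)`` (ISI in s).

    ``c`` is the predicted recovery at a 1 s ISI (ln 1 = 0) and
    summarizes long-term recovery.  The log-linear form is a heuristic
    for short-to-medium ISIs and is not meant to extrapolate far beyond
    ~1 s.
    """
    x = np.asarray(isi_s, dtype=float)
    y = np.asarray(recovery, dtype=float)
    if np.any(x <= 0):
        raise ValueError("ISIs must be positive")
    if np.unique(x).size < 2:
        raise ValueError("at least two distinct ISIs are required")
    A = np.column_stack([np.ones_like(x), np.log(x)])
    coef, *_ = np.linalg.lstsq(A, y, rcond=None)
    return float(coef[0]), float(coef[1])


def compute_recovery_curve(rep_tcs: Mapping[int, np.ndarray],
                           dur134_tc: np.ndarray, fs: float,
                           onset_index: int,
                           isis_s: Optional[Sequence[float]] = None,
                           clip_negative: bool = True) -> RecoveryCurve:
    """Second-response isolation + AUC ratios + log-linear fit, in one go."""
    if isis_s is None:
        isis_s = [float(x) for x in canonical_isis()]
    ests = estimate_second_response(rep_tcs, dur134_tc, fs, onset_index,
                                    isis_s)
    ratios = [recovery_ratio(ests[lv], clip_negative=clip_negative)
              for lv in sorted(ests)]
    c, a = fit_recovery_curve(isis_s, ratios)
    return RecoveryCurve(np.asarray(isis_s), np.asarray(ratios), c, a)
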