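"""Temporal conditions, trial sequences and sampled stimulus time courses.

The experiment presents natural images in two trial types at a 60 Hz
monitor refresh: *duration* trials show a single stimulus for one of six
durations (powers of two monitor frames: 1, 2, 4, 8, 16, 32 frames), and
*repetition* trials show the same image twice for 8 frames (the "134 ms"
condition) separated by one of six inter-stimulus intervals (ISIs) with
the same power-of-two spacing.  Six image categories times 12 temporal
conditions give the 72 conditions the model is fitted to.

Durations are represented internally as exact rationals ``2**k / 60``
seconds; the familiar millisecond labels (17/33/67/134/267/533) are
display rounding only.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from fractions import Fraction
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

#: The six image categories, in canonical order.
CATEGORIES: tuple[str, ...] = (
    "bodies", "buildings", "faces", "objects", "scenes", "scrambled",
)

MONITOR_HZ = 60
N_LEVELS = 6
#: Stimulus duration of every repetition-trial pulse, in monitor frames.
REPETITION_DURATION_FRAMES = 8
#: Exemplars per category in the stimulus set (6 x 48 = 288 images).
N_EXEMPLARS_PER_CATEGORY = 48
#: Inter-trial interval range in seconds (uniform draw).
ITI_RANGE_S = (1.25, 1.75)
#: Display labels in ms for levels 0..5 (rounded as conventionally printed).
DISPLAY_MS = (17, 33, 67, 134, 267, 533)

TRIALS_PER_RUN = 144
#: Default epoch around trial onset, seconds.
DEFAULT_EPOCH_S = (-0.1, 1.5)


def round_half_away(x: float) -> int:
    """Round to nearest integer, halves away from zero."""
    if x >= 0:
        return int(math.floor(x + 0.5))
    return int(math.ceil(x - 0.5))


@dataclass(frozen=True)
class TemporalCondition:
    """One of the 12 temporal conditions (6 durations + 6 ISIs)."""

    kind: str                     # "duration" | "repetition"
    level: int                    # 0..5, value = 2**level frames
    duration_s: Fraction          # stimulus duration (per pulse)
    isi_s: Optional[Fraction] = None   # repetition trials only

    def __post_init__(self) -> None:
        if self.kind not in ("duration", "repetition"):
            raise ValueError(f"unknown trial kind {self.kind!r}")
        if not 0 <= self.level < N_LEVELS:
            raise ValueError(f"level must be in 0..{N_LEVELS - 1}, got {self.level}")
        if self.kind == "repetition" and self.isi_s is None:
            raise ValueError("repetition conditions require isi_s")

    @property
    def label(self) -> str:
        if self.kind == "duration":
            return f"dur{DISPLAY_MS[self.level]}"
        return f"isi{DISPLAY_MS[self.level]}"

    @property
    def total_span_s(self) -> Fraction:
        """Stimulus span from first onset to last offset."""
        if self.kind == "duration":
            return self.duration_s
        return self.duration_s + self.isi_s + self.duration_s


@dataclass(frozen=True)
class TrialSpec:
    condition: TemporalCondition
    category: str
    exemplar_id: int
    iti_s: float

    def __post_init__(self) -> None:
        if self.category not in CATEGORIES:
            raise ValueError(f"unknown category {self.category!r}")
        if not ITI_RANGE_S[0] <= self.iti_s <= ITI_RANGE_S[1]:
            raise ValueError(f"iti_s {self.iti_s} outside {ITI_RANGE_S}")


@dataclass
class StimulusTimecourse:
    """Sampled stimulus drive ``s``: 0 when absent, amplitude when present."""

    fs: float
    onset_index: int
    values: np.ndarray
    pulses: list = field(default_factory=list)   # (start, stop) sample pairs

    def scaled(self, factor: float) -> "StimulusTimecourse":
        return StimulusTimecourse(self.fs, self.onset_index,
                                  self.values * factor, list(self.pulses))


def canonical_durations() -> list[Fraction]:
    """The six stimulus durations 2**k/60 s, k = 0..5, as exact rationals."""
    return [Fraction(2 ** k, MONITOR_HZ) for k in range(N_LEVELS)]


def canonical_isis() -> list[Fraction]:
    """The six inter-stimulus intervals (same power-of-two spacing)."""
    return canonical_durations()


def temporal_conditions() -> list[TemporalCondition]:
    """All 12 temporal conditions: 6 durations then 6 ISIs."""
    rep_dur = Fraction(REPETITION_DURATION_FRAMES, MONITOR_HZ)
    conds = [TemporalCondition("duration", k, d)
             for k, d in enumerate(canonical_durations())]
    conds += [TemporalCondition("repetition", k, rep_dur, isi)
              for k, isi in enumerate(canonical_isis())]
    return conds


def stimulus_set_size() -> int:
    """Total number of exemplar images across categories."""
    return len(CATEGORIES) * N_EXEMPLARS_PER_CATEGORY


def make_stimulus_timecourse(cond: TemporalCondition, fs: float,
                             epoch_len_s: float = DEFAULT_EPOCH_S[1] - DEFAULT_EPOCH_S[0],
                             onset_s: float = -DEFAULT_EPOCH_S[0],
                             amplitude: float = 1.0) -> StimulusTimecourse:
    """Sample a condition's stimulus drive on a regular grid.

    Duration trials yield a single pulse of ``round(duration*fs)`` samples;
    repetition trials yield two pulses of ``round((8/60)*fs)`` samples
    separated by ``round(isi*fs)`` zero samples.  Rounding is
    half-away-from-zero.
    """
    if fs <= 0:
        raise ValueError("fs must be positive")
    if onset_s + float(cond.total_span_s) > epoch_len_s + 1e-12:
        raise ValueError(
            f"condition {cond.label} spans past the epoch: onset {onset_s} s + "
            f"{float(cond.total_span_s):.4f} s > {epoch_len_s} s")
    n = round_half_away(epoch_len_s * fs)
    onset = round_half_away(onset_s * fs)
    values = np.zeros(n)
    pulses: list[tuple[int, int]] = []
    width = round_half_away(float(cond.duration_s) * fs)
    if cond.kind == "duration":
        pulses.append((onset, onset + width))
    else:
        gap = round_half_away(float(cond.isi_s) * fs)
        pulses.append((onset, onset + width))
        start2 = onset + width + gap
        pulses.append((start2, start2 + width))
    for a, b in pulses:
        values[a:b] = amplitude
    return StimulusTimecourse(fs, onset, values, pulses)


def make_run(seed: int) -> list[TrialSpec]:
    """A randomized run of 144 trials: 72 duration + 72 repetition.

    Each trial type contains 12 stimuli of every category (each of the 36
    kind-level-category cells occurs twice).  Exemplars are drawn uniformly
    without replacement within the run; ITIs are uniform(1.25, 1.75).
    """
    rng = np.random.default_rng(seed)
    conds = temporal_conditions()
    # each (condition, category) cell twice -> 12 * 6 * 2 = 144
    cells = [(c, cat) for c in conds for cat in CATEGORIES for _ in range(2)]
    order = rng.permutation(len(cells))
    itis = rng.uniform(*ITI_RANGE_S, size=len(cells))
    # 24 exemplars per category per run, without replacement
    exemplars = {cat: list(rng.choice(N_EXEMPLARS_PER_CATEGORY, size=24,
                                      replace=False))
                 for cat in CATEGORIES}
    trials = []
    for i, idx in enumerate(order):
        cond, cat = cells[idx]
        trials.append(TrialSpec(cond, cat, int(exemplars[cat].pop()),
                                float(itis[i])))
    return trials


def events_table(run: Sequence[TrialSpec], start_s: float = 1.0) -> pd.DataFrame:
    """Tabulate a run as an event table with cumulative onsets in seconds."""
    rows = []
    t = start_s
    for trial in run:
        cond = trial.condition
        rows.append({
            "onset": t,
            "duration": float(cond.duration_s),
            "trial_type": cond.kind,
            "level": cond.level,
            "isi": float(cond.isi_s) if cond.isi_s is not None else np.nan,
            "category": trial.category,
            "exemplar_id": trial.exemplar_id,
            "iti": trial.iti_s,
        })
        t += float(cond.total_span_s) + trial.iti_s
    return pd.DataFrame(rows)


def write_events(df: pd.DataFrame, path: str | Path) -> None:
    """Write an event table as TSV (onsets in seconds, 0-based samples)."""
    path = Path(path)
    with path.open("w") as fh:
        fh.write("# onset/duration/isi/iti in seconds; sample indices are "
                 "0-based\n")
        df.to_csv(fh, sep="\t", index=False)


def read_events(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", comment="#")
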