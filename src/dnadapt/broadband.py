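"""Voltage to time-varying broadband: re-referencing, filterbank power,
epoching, baseline correction and trial rejection.

The broadband (high-gamma) signal is extracted per channel by band-pass
filtering the common-average-re-referenced voltage into 10 Hz-wide bands
between 50 and 200 Hz (dropping bands whose closed interval contains a
line-noise frequency: 60, 120, 180 Hz), computing each band's power
envelope as the squared magnitude of the analytic signal, and averaging
the band envelopes with the geometric mean so the 1/f spectrum does not
let low bands dominate.  Filtering is zero-phase (forward-backward
Butterworth, order chosen automatically to meet a < 3 dB passband ripple
and 60 dB stopband attenuation spec) so group delay does not differ
across bands.

Epochs are then cut around stimulus onsets and converted to percent
signal change against the mean pre-stimulus baseline pooled across all
epochs of a run; trials whose maximum exceeds mean + 2 SD of the
per-trial maxima are rejected.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
from scipy.signal import butter, buttord, hilbert, sosfiltfilt

from .trial_design import round_half_away

__all__ = [
    "VoltageRecording", "BandDefinition", "EpochedBroadband",
    "common_average_rereference", "band_definitions", "band_power_envelope",
    "broadband_geomean", "compute_broadband", "epoch_and_baseline",
    "reject_trials",
]

LINE_NOISE_HZ = (60.0, 120.0, 180.0)


@dataclass
class VoltageRecording:
    """Multichannel voltage, channels x samples, with per-channel group."""

    fs: float
    data: np.ndarray
    groups: Sequence[str]

    def __post_init__(self) -> None:
        self.data = np.atleast_2d(np.asarray(self.data, dtype=float))
        if self.fs <= 0:
            raise ValueError("fs must be positive")
        if len(self.groups) != self.data.shape[0]:
            raise ValueError("one group label per channel is required")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("voltage data must be finite")


@dataclass(frozen=True)
class BandDefinition:
    lo: float
    hi: float

    def __post_init__(self) -> None:
        if not 0 < self.lo < self.hi:
            raise ValueError(f"need 0 < lo < hi, got [{self.lo}, {self.hi}]")

    def contains(self, f: float) -> bool:
        return self.lo <= f <= self.hi   # closed interval


@dataclass
class EpochedBroadband:
    fs: float
    data: np.ndarray              # trials x samples
    onset_index: int              # stimulus onset within the epoch
    window_s: tuple[float, float]
    units: str = "percent signal change"


def common_average_rereference(rec: VoltageRecording) -> VoltageRecording:
    """Subtract each electrode group's across-channel mean per sample."""
    out = rec.data.copy()
    groups = np.asarray(rec.groups)
    for g in np.unique(groups):
        sel = groups == g
        if not sel.any():
            raise ValueError(f"empty electrode group {g!r}")
        out[sel] -= out[sel].mean(axis=0, keepdims=True)
    return VoltageRecording(rec.fs, out, list(rec.groups))


def band_definitions(lo: float = 50.0, hi: float = 200.0, width: float = 10.0,
                     noise: Sequence[float] = LINE_NOISE_HZ
                     ) -> list[BandDefinition]:
    """Contiguous bands [lo+i*w, lo+(i+1)*w], dropping any band whose
    closed interval contains a line-noise frequency."""
    n = (hi - lo) / width
    if abs(n - round(n)) > 1e-9:
        raise ValueError("(hi - lo) must be divisible by width")
    bands = [BandDefinition(lo + i * width, lo + (i + 1) * width)
             for i in range(int(round(n)))]
    return [b for b in bands if not any(b.contains(f) for f in noise)]


def _bandpass_sos(band: BandDefinition, fs: float, gpass: float = 3.0,
                  gstop: float = 60.0) -> np.ndarray:
    """Butterworth band-pass meeting the ripple/attenuation spec, with
    stopband edges one band-width outside the passband."""
    nyq = fs / 2.0
    if band.hi >= nyq:
        raise ValueError(f"band [{band.lo}, {band.hi}] reaches the Nyquist "
                         f"frequency {nyq}")
    width = band.hi - band.lo
    ws = [max(band.lo - width, 1e-3), min(band.hi + width, nyq * 0.999)]
    order, wn = buttord([band.lo, band.hi], ws, gpass, gstop, fs=fs)
    return butter(order, wn, btype="bandpass", output="sos", fs=fs)


def band_power_envelope(x: np.ndarray, band: BandDefinition, fs: float,
                        power: float = 2.0) -> np.ndarray:
    """Zero-phase band-pass then |analytic signal|**power (default: power
    envelope, i.e. squared magnitude)."""
    x = np.asarray(x, dtype=float)
    sos = _bandpass_sos(band, fs)
    filtered = sosfiltfilt(sos, x)
    return np.abs(hilbert(filtered)) ** power


def broadband_geomean(envelopes: np.ndarray,
                      floor: Optional[float] = None) -> np.ndarray:
    """Per-sample geometric mean across bands with a small floor so a
    zero sample in one band does not annihilate the average."""
    env = np.asarray(envelopes, dtype=float)
    if np.any(env < 0):
        raise ValueError("envelopes must be nonnegative")
    if floor is None:
        scale = env.max() if env.size and env.max() > 0 else 1.0
        floor = scale * np.finfo(float).eps
    return np.exp(np.mean(np.log(np.maximum(env, floor)), axis=0))


def compute_broadband(rec: VoltageRecording,
                      bands: Optional[Sequence[BandDefinition]] = None
                      ) -> np.ndarray:
    """Broadband time course per channel (channels x samples)."""
    if bands is None:
        bands = band_definitions()
    out = np.empty_like(rec.data)
    for ch in range(rec.data.shape[0]):
        envs = np.stack([band_power_envelope(rec.data[ch], b, rec.fs)
                         for b in bands])
        out[ch] = broadband_geomean(envs)
    return out


def epoch_and_baseline(bb: np.ndarray, onsets: Sequence[int], fs: float,
                       window_s: tuple[float, float] = (-0.1, 1.5),
                       baseline_s: tuple[float, float] = (-0.1, 0.0)
                       ) -> EpochedBroadband:
    """Cut epochs around onsets (sample indices) and convert to percent
    signal change against the run-pooled pre-stimulus baseline."""
    bb = np.asarray(bb, dtype=float)
    start_off = round_half_away(window_s[0] * fs)
    stop_off = round_half_away(window_s[1] * fs)
    epochs = []
    for onset in onsets:
        a, b = onset + start_off, onset + stop_off
        if a < 0 or b > bb.size:
            raise ValueError(f"epoch around onset {onset} exceeds the "
                             "recording bounds")
        epochs.append(bb[a:b])
    data = np.stack(epochs)
    onset_index = -start_off
    b0 = onset_index + round_half_away(baseline_s[0] * fs)
    b1 = onset_index + round_half_away(baseline_s[1] * fs)
    base = data[:, b0:b1].mean()
    if base <= 0:
        raise ValueError("baseline mean must be positive for percent "
                         "signal change")
    return EpochedBroadband(fs, (data - base) / base * 100.0, onset_index,
                            window_s)


def reject_trials(epochs: EpochedBroadband
                  ) -> tuple[np.ndarray, np.ndarray]:
    """Reject trials whose maximum exceeds mean + 2 SD of per-trial maxima.

    Returns (kept_indices, rejected_indices).
    """
    n = epochs.data.shape[0]
    if n < 3:
        raise ValueError("at least 3 trials are required for rejection")
    maxima = epochs.data.max(axis=1)
    thr = maxima.mean() + 2.0 * maxima.std(ddof=1)
    rejected = np.flatnonzero(maxima > thr)
    kept = np.flatnonzero(maxima <= thr)
    return kept, rejected
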