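"""Synthetic data with known ground truth.

Two generators drive all tests and harnesses:

* :func:`generate_condition_responses` -- trial-averaged 72-condition
  broadband responses produced by the csDN forward model plus i.i.d.
  Gaussian noise on the broadband scale (noise SD expressed as a
  fraction of the electrode's peak prediction, averaged over a
  configurable number of trials per condition);
* :func:`generate_voltage_session` -- raw multichannel voltage whose
  50-200 Hz carrier amplitude is modulated by the square root of the
  csDN prediction (so extracted *power* tracks the prediction), on top
  of 1/f background noise and 60/120/180 Hz line components.

Three area presets order the DN time constants and exponent from an
early-visual-like regime to a lateral-occipital-like regime (tau1, tau2
and n all increase), which makes the forward model's time-to-peak and
FWHM increase and its long-term recovery decrease across the presets.
Preset values are conventions of this package chosen to land in a
physiologically plausible regime; they are not measured values.

Every generator is a pure function of its configuration and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .trial_design import (CATEGORIES, DEFAULT_EPOCH_S, TrialSpec,
                           make_stimulus_timecourse, temporal_conditions,
                           round_half_away)
from .dn_model import CategoryScaling, DNParams, csdn_forward
from .model_fitting import (ConditionResponseSet, FitConfig, fit_electrode,
                            gauge_normalized)

__all__ = [
    "AREAS", "GroundTruthElectrode", "area_presets",
    "generate_condition_responses", "generate_voltage_session",
    "generate_cohort", "parameter_recovery_report",
]

AREAS = ("V1V3like", "VOTClike", "LOTClike")

_PRESETS: dict[str, DNParams] = {
    "V1V3like": DNParams(tau1=0.02, tau2=0.08, n=1.2, sigma=0.03,
                         shift=0.03, scale=2.0),
    "VOTClike": DNParams(tau1=0.04, tau2=0.10, n=1.5, sigma=0.05,
                         shift=0.04, scale=2.0),
    "LOTClike": DNParams(tau1=0.08, tau2=0.12, n=1.8, sigma=0.08,
                         shift=0.05, scale=2.0),
}


def area_presets() -> dict[str, DNParams]:
    """DN parameter presets per simulated area (tau1, tau2, n increase
    from early to lateral-occipital-like)."""
    return {k: replace(v) for k, v in _PRESETS.items()}


@dataclass
class GroundTruthElectrode:
    """Everything needed to regenerate one synthetic electrode."""

    params: DNParams
    scalings: CategoryScaling
    area: str = "V1V3like"
    noise_sd: float = 0.05            # fraction of the peak prediction
    n_trials_per_condition: int = 8
    electrode_id: str = "e0"

    def __post_init__(self) -> None:
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be >= 0")
        if self.n_trials_per_condition < 1:
            raise ValueError("n_trials_per_condition must be >= 1")

    def to_dict(self) -> dict:
        d = {"area": self.area, "noise_sd": self.noise_sd,
             "n_trials_per_condition": self.n_trials_per_condition,
             "electrode_id": self.electrode_id, **self.params.to_dict()}
        d.update({f"sf_{c}": self.scalings[c] for c in CATEGORIES})
        return d


def generate_condition_responses(gt: GroundTruthElectrode, seed: int,
                                 fs: float = 512.0,
                                 epoch_s: tuple[float, float] = DEFAULT_EPOCH_S,
                                 noise_dist: str = "gaussian"
                                 ) -> ConditionResponseSet:
    """Trial-averaged responses for all 72 conditions of one electrode.

    ``noise_dist`` selects the trial-noise family: "gaussian" (default)
    or "laplace", a heavier-tailed alternative for robustness checks
    (both zero-mean with SD ``noise_sd * peak``).
    """
    if noise_dist not in ("gaussian", "laplace"):
        raise ValueError(f"unknown noise_dist {noise_dist!r}")
    rng = np.random.default_rng(seed)
    onset_s = -epoch_s[0]
    epoch_len = epoch_s[1] - epoch_s[0]
    preds = {}
    for cond in temporal_conditions():
        stim = make_stimulus_timecourse(cond, fs, epoch_len, onset_s)
        for cat in CATEGORIES:
            preds[(cond.kind, cond.level, cat)] = csdn_forward(
                stim, gt.params, gt.scalings, cat).values
    peak = max(p.max() for p in preds.values())
    responses = {}
    for key in sorted(preds):
        p = preds[key]
        if gt.noise_sd > 0:
            shape = (gt.n_trials_per_condition, p.size)
            sd = gt.noise_sd * peak
            if noise_dist == "gaussian":
                noise = rng.normal(0.0, sd, size=shape)
            else:
                noise = rng.laplace(0.0, sd / np.sqrt(2), size=shape)
            responses[key] = (p + noise).mean(axis=0)
        else:
            responses[key] = p.copy()
    return ConditionResponseSet(fs=fs, onset_s=onset_s, responses=responses,
                                electrode_id=gt.electrode_id, area=gt.area)


def _pink_noise(n: int, rng: np.random.Generator) -> np.ndarray:
    """1/f-amplitude noise, unit standard deviation."""
    white = rng.standard_normal(n)
    spec = np.fft.rfft(white)
    f = np.fft.rfftfreq(n)
    f[0] = f[1] if n > 1 else 1.0
    pink = np.fft.irfft(spec / np.sqrt(f), n)
    return pink / pink.std()


def _bandlimited_noise(n: int, fs: float, lo: float, hi: float,
                       rng: np.random.Generator) -> np.ndarray:
    from scipy.signal import butter, sosfiltfilt
    sos = butter(4, [lo, hi], btype="bandpass", output="sos", fs=fs)
    x = sosfiltfilt(sos, rng.standard_normal(n))
    return x / x.std()


def generate_voltage_session(gt: GroundTruthElectrode,
                             run: Sequence[TrialSpec], fs: float = 512.0,
                             seed: int = 0, n_channels: int = 4,
                             pink_amp: float = 0.5, line_amp: float = 1.0,
                             modulation_depth: float = 3.0,
                             epoch_s: tuple[float, float] = DEFAULT_EPOCH_S,
                             start_s: float = 1.0
                             ) -> tuple["VoltageRecording", pd.DataFrame,
                                        np.ndarray]:
    """Simulate a raw voltage session for a run of trials.

    Channel 0 carries the modulated high-gamma signal: a 50-200 Hz
    carrier whose amplitude is sqrt(1 + depth * prediction / peak), so
    carrier *power* tracks the csDN prediction.  Remaining channels
    carry unmodulated carrier.  All channels share the line components
    and have independent 1/f backgrounds, and belong to one electrode
    group.  Returns (recording, event table, known power modulator).

    Independent random substreams per component keep e.g. the carrier
    identical when only ``line_amp`` changes.
    """
    from .broadband import VoltageRecording

    ss = np.random.SeedSequence(seed)
    streams = [np.random.default_rng(s) for s in ss.spawn(2 * n_channels + 1)]
    rng_phase = streams[0]
    carrier_rngs = streams[1:1 + n_channels]
    pink_rngs = streams[1 + n_channels:]

    onset_s = -epoch_s[0]
    epoch_len = epoch_s[1] - epoch_s[0]
    rows = []
    t = start_s
    for trial in run:
        rows.append({"onset": t, "trial_type": trial.condition.kind,
                     "level": trial.condition.level,
                     "category": trial.category})
        t += float(trial.condition.total_span_s) + trial.iti_s
    total_s = t + epoch_len
    n = int(np.ceil(total_s * fs))

    drive = np.zeros(n)
    for trial, row in zip(run, rows):
        stim = make_stimulus_timecourse(trial.condition, fs, epoch_len,
                                        onset_s)
        pred = csdn_forward(stim, gt.params, gt.scalings,
                            trial.category).values
        start = round_half_away(row["onset"] * fs) - stim.onset_index
        drive[start:start + pred.size] += pred
    peak = drive.max()
    modulator = 1.0 + (modulation_depth * drive / peak if peak > 0 else 0.0)

    tt = np.arange(n) / fs
    lines = sum(line_amp * np.sin(2 * np.pi * f * tt
                                  + rng_phase.uniform(0, 2 * np.pi))
                for f in (60.0, 120.0, 180.0))
    data = np.empty((n_channels, n))
    for ch in range(n_channels):
        carrier = _bandlimited_noise(n, fs, 50.0, 200.0, carrier_rngs[ch])
        if ch == 0:
            carrier = carrier * np.sqrt(modulator)
        data[ch] = carrier + pink_amp * _pink_noise(n, pink_rngs[ch]) + lines

    events = pd.DataFrame(rows)
    events["onset_index"] = [round_half_away(o * fs)
                             for o in events["onset"]]
    rec = VoltageRecording(fs, data, ["grid"] * n_channels)
    return rec, events, modulator


def generate_cohort(n_per_area: int, seed: int, fs: float = 512.0,
                    noise_sd: float = 0.05, n_trials: int = 8,
                    sf_spread: float = 0.3,
                    epoch_s: tuple[float, float] = DEFAULT_EPOCH_S
                    ) -> list[tuple[GroundTruthElectrode,
                                    ConditionResponseSet]]:
    """A multi-area synthetic cohort with heterogeneous category scalings.

    DN parameters are jittered multiplicatively (+-15%) around the area
    presets; category scaling factors are log-normal around 1 with
    log-SD ``sf_spread`` and gauge-normalized to mean 1.
    """
    ss = np.random.SeedSequence(seed)
    cohort = []
    presets = area_presets()
    idx = 0
    for area in AREAS:
        for j in range(n_per_area):
            child = np.random.SeedSequence(entropy=ss.entropy,
                                           spawn_key=(idx,))
            rng = np.random.default_rng(child)
            base = presets[area]
            jit = rng.uniform(0.85, 1.15, size=4)
            params = DNParams(base.tau1 * jit[0], base.tau2 * jit[1],
                              base.n * jit[2], base.sigma * jit[3],
                              base.shift, base.scale)
            sf = np.exp(rng.normal(0.0, sf_spread, size=len(CATEGORIES)))
            sf = sf / sf.mean()
            gt = GroundTruthElectrode(
                params=params, scalings=CategoryScaling.from_vector(sf),
                area=area, noise_sd=noise_sd,
                n_trials_per_condition=n_trials,
                electrode_id=f"{area}_{j:02d}")
            data_seed = int(rng.integers(0, 2 ** 31 - 1))
            cohort.append((gt, generate_condition_responses(
                gt, data_seed, fs=fs, epoch_s=epoch_s)))
            idx += 1
    return cohort


_RECOVERED = ("tau1", "tau2", "n", "sigma")


def parameter_recovery_report(n_per_area: int = 20,
                              noise_levels: Sequence[float] = (0.0, 0.05),
                              seed: int = 0, fs: float = 128.0,
                              n_trials: int = 8,
                              fit_config: Optional[FitConfig] = None,
                              compute_cv: bool = True,
                              progress: bool = False) -> pd.DataFrame:
    """Fit csDN to synthetic electrodes and tabulate recovery errors.

    One row per (electrode, noise level) with gauge-normalized relative
    errors of tau1/tau2/n/sigma, whether the category-scaling rank order
    (largest sf) was recovered, and the cross-validated R^2.  This is
    the package's primary self-validation harness.
    """
    rows = []
    for noise in noise_levels:
        cohort = generate_cohort(n_per_area, seed=seed, fs=fs,
                                 noise_sd=noise, n_trials=n_trials)
        for gt, data in cohort:
            cfg = fit_config or FitConfig(model="csdn", seed=seed)
            fit = fit_electrode(data, cfg, compute_cv=compute_cv)
            p_est, cs_est = gauge_normalized(fit.params, fit.scalings)
            p_true, cs_true = gauge_normalized(gt.params, gt.scalings)
            row = {"area": gt.area, "noise_sd": noise,
                   "electrode_id": gt.electrode_id, "r2_cv": fit.r2_cv,
                   "converged": fit.converged}
            for name in _RECOVERED:
                tru, est = getattr(p_true, name), getattr(p_est, name)
                row[f"{name}_true"] = tru
                row[f"{name}_est"] = est
                row[f"{name}_rel_err"] = abs(est - tru) / abs(tru)
            row["sf_rank_ok"] = bool(
                int(np.argmax(cs_est.as_vector()))
                == int(np.argmax(cs_true.as_vector())))
            rows.append(row)
            if progress:
                print(f"  fitted {gt.electrode_id} @ noise {noise}: "
                      f"r2_cv={fit.r2_cv:.4f}")
    return pd.DataFrame(rows)
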