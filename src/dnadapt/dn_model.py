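"""Delayed divisive normalization (DN) forward model.

The model maps a stimulus time course ``s(t)`` to a predicted broadband
response through a linear-nonlinear-gain-control cascade:

* linear:      ``rL = s * h1(tau1)`` with a gamma impulse response
  ``h1(t) = t exp(-t/tau1)`` (peaks at ``t = tau1``),
* nonlinear:   input drive ``|rL|**n`` (full-wave rectification and
  exponentiation),
* gain control: divisive normalization by a delayed copy of the drive,
  ``sigma**n + |rL * h2(tau2)|**n`` with the low-pass filter
  ``h2(t) = exp(-t/tau2)``,

followed by an onset ``shift`` (integer-sample delay of the output) and a
multiplicative ``scale``.  The delayed denominator produces the
characteristic transient-then-sustained response shape and repetition
suppression for paired pulses.

The category-selective variant (csDN) multiplies the stimulus time course
by a per-category scaling factor ``sf`` before the cascade, so a single
parameter set plus six scalars predicts all 72 conditions.

Both kernels are normalized to unit sum.  This is a convention (it makes
the sustained-stimulus steady state exactly ``scale / (1 + sigma**n)`` and
keeps ``sigma`` comparable across sampling rates); pass
``normalize=False`` to sample the raw kernels.

Note an exact invariance of the csDN parameterization: scaling all six
``sf`` by a constant ``alpha`` while scaling ``sigma`` by the same
``alpha`` leaves every prediction unchanged (numerator and denominator
both pick up ``alpha**n``).  Only the gauge-fixed combination (for
example with mean ``sf`` set to 1) is identifiable from data.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from typing import Mapping, Optional

import numpy as np
from scipy.signal import fftconvolve

from .trial_design import CATEGORIES, StimulusTimecourse, round_half_away

__all__ = [
    "DNParams", "CategoryScaling", "ModelPrediction",
    "gamma_irf", "exp_decay", "linear_response",
    "dn_forward", "csdn_forward", "dn_forward_batch",
]

#: Maximum fraction of kernel mass allowed beyond the sampled support.
MAX_TRUNCATED_MASS = 0.01


@dataclass
class DNParams:
    """Free parameters of the DN model.

    tau1   -- IRF time constant, seconds (peak latency of h1)
    tau2   -- delay (low-pass) time constant, seconds
    n      -- exponent applied to drive and normalization pool
    sigma  -- semi-saturation constant (gain floor of the pool)
    shift  -- response-onset delay, seconds (>= 0)
    scale  -- electrode-specific gain
    """

    tau1: float
    tau2: float
    n: float
    sigma: float
    shift: float = 0.0
    scale: float = 1.0

    def __post_init__(self) -> None:
        for name in ("tau1", "tau2", "n", "sigma", "scale"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive, got "
                                 f"{getattr(self, name)}")
        if self.shift < 0:
            raise ValueError(f"shift must be >= 0, got {self.shift}")

    def to_dict(self) -> dict:
        return asdict(self)


@dataclass
class CategoryScaling:
    """Per-category multiplier on the stimulus time course (csDN)."""

    sf: Mapping[str, float]

    def __post_init__(self) -> None:
        missing = set(CATEGORIES) - set(self.sf)
        if missing:
            raise ValueError(f"missing categories: {sorted(missing)}")
        extra = set(self.sf) - set(CATEGORIES)
        if extra:
            raise ValueError(f"unknown categories: {sorted(extra)}")
        for cat, v in self.sf.items():
            if v < 0:
                raise ValueError(f"sf[{cat}] must be >= 0, got {v}")

    def __getitem__(self, category: str) -> float:
        if category not in self.sf:
            raise KeyError(f"unknown category {category!r}; valid: "
                           f"{list(CATEGORIES)}")
        return float(self.sf[category])

    def as_vector(self) -> np.ndarray:
        """sf values in canonical category order."""
        return np.array([self.sf[c] for c in CATEGORIES])

    @classmethod
    def uniform(cls, value: float = 1.0) -> "CategoryScaling":
        return cls({c: value for c in CATEGORIES})

    @classmethod
    def from_vector(cls, vec) -> "CategoryScaling":
        return cls(dict(zip(CATEGORIES, map(float, vec))))


@dataclass
class ModelPrediction:
    fs: float
    values: np.ndarray
    components: Optional[dict] = None


def _kernel_grid(support_s: float, fs: float) -> np.ndarray:
    n = int(np.ceil(support_s * fs)) + 1
    return np.arange(n) / fs


def gamma_irf(tau1: float, fs: float, support_s: Optional[float] = None,
              normalize: bool = True) -> np.ndarray:
    """Gamma impulse response ``t exp(-t/tau1)`` sampled on [0, support].

    Raises if the un-sampled tail beyond ``support_s`` holds more than 1%
    of the kernel's mass (for this kernel that needs support >~ 6.6 tau1;
    the default support is 8 tau1).
    """
    if tau1 <= 0:
        raise ValueError("tau1 must be positive")
    if support_s is None:
        support_s = 8.0 * tau1
    # analytic tail mass of t*exp(-t/tau): (1 + T/tau) * exp(-T/tau)
    x = support_s / tau1
    if (1.0 + x) * np.exp(-x) > MAX_TRUNCATED_MASS:
        raise ValueError(
            f"kernel support {support_s:.4g} s truncates more than "
            f"{MAX_TRUNCATED_MASS:.0%} of the gamma IRF mass for tau1={tau1}")
    t = _kernel_grid(support_s, fs)
    k = t * np.exp(-t / tau1)
    return k / k.sum() if normalize else k


def exp_decay(tau2: float, fs: float, support_s: Optional[float] = None,
              normalize: bool = True) -> np.ndarray:
    """Decaying-exponential low-pass kernel ``exp(-t/tau2)`` on [0, support]."""
    if tau2 <= 0:
        raise ValueError("tau2 must be positive")
    if support_s is None:
        support_s = 5.0 * tau2
    if np.exp(-support_s / tau2) > MAX_TRUNCATED_MASS:
        raise ValueError(
            f"kernel support {support_s:.4g} s truncates more than "
            f"{MAX_TRUNCATED_MASS:.0%} of the exponential kernel mass for "
            f"tau2={tau2}")
    t = _kernel_grid(support_s, fs)
    k = np.exp(-t / tau2)
    return k / k.sum() if normalize else k


def _causal_conv(x: np.ndarray, kernel: np.ndarray) -> np.ndarray:
    """Causal convolution truncated to the input length (zero initial state).

    Works on the last axis so stacked condition matrices convolve in one
    call.
    """
    full = fftconvolve(x, kernel if x.ndim == 1 else kernel[None, :],
                       axes=-1 if x.ndim > 1 else None)
    return full[..., : x.shape[-1]]


def linear_response(stim: StimulusTimecourse, tau1: float) -> np.ndarray:
    """Linear stage ``rL = s * h1(tau1)`` (causal, input-length output)."""
    return _causal_conv(stim.values, gamma_irf(tau1, stim.fs))


def _apply_shift(values: np.ndarray, shift_s: float, fs: float) -> np.ndarray:
    """Delay the response by ``shift_s`` seconds, zero-padding the onset.

    The delay is fractional-sample (linear interpolation between the two
    neighbouring integer delays): at integer multiples of the sampling
    period it reduces to an exact sample shift, and in between it keeps
    the least-squares objective smooth in ``shift`` so the nuisance
    parameter is actually fittable by gradient-based optimizers.
    """
    k = shift_s * fs
    i = int(np.floor(k))
    frac = k - i

    def _delay(x, d):
        if d == 0:
            return x
        out = np.zeros_like(x)
        out[..., d:] = x[..., :-d]
        return out

    if frac == 0.0:
        return _delay(values, i)
    return (1.0 - frac) * _delay(values, i) + frac * _delay(values, i + 1)


def dn_forward(stim: StimulusTimecourse, p: DNParams,
               keep_components: bool = False) -> ModelPrediction:
    """Full DN cascade on one stimulus time course."""
    rL = linear_response(stim, p.tau1)
    drive = np.abs(rL) ** p.n
    delayed = _causal_conv(rL, exp_decay(p.tau2, stim.fs))
    pool = p.sigma ** p.n + np.abs(delayed) ** p.n
    r = drive / pool
    r = p.scale * _apply_shift(r, p.shift, stim.fs)
    if not np.all(np.isfinite(r)):
        raise FloatingPointError(f"non-finite DN output for parameters {p}")
    comps = None
    if keep_components:
        comps = {"linear": rL, "input_drive": drive,
                 "normalization_pool": pool}
    return ModelPrediction(stim.fs, r, comps)


def csdn_forward(stim: StimulusTimecourse, p: DNParams, cs: CategoryScaling,
                 category: str, keep_components: bool = False) -> ModelPrediction:
    """Category-selective DN: DN applied to ``s * sf[category]``."""
    if category not in CATEGORIES:
        raise KeyError(f"unknown category {category!r}; valid: "
                       f"{list(CATEGORIES)}")
    return dn_forward(stim.scaled(cs[category]), p, keep_components)


def dn_forward_batch(stim_matrix: np.ndarray, fs: float, p: DNParams,
                     sf: Optional[np.ndarray] = None) -> np.ndarray:
    """Vectorized forward pass over stacked stimulus conditions.

    ``stim_matrix`` is (n_conditions, T); ``sf`` an optional vector of
    stimulus amplitudes (e.g. the six category scalings).  Because the
    linear stage is linear in the stimulus, the two convolutions are done
    once on the base conditions and the scalings broadcast afterwards.
    Returns (len(sf), n_conditions, T), or (n_conditions, T) when ``sf``
    is None.
    """
    rL = _causal_conv(stim_matrix, gamma_irf(p.tau1, fs))
    delayed = _causal_conv(rL, exp_decay(p.tau2, fs))
    if sf is None:
        drive = np.abs(rL) ** p.n
        pool = p.sigma ** p.n + np.abs(delayed) ** p.n
    else:
        sf = np.asarray(sf, dtype=float)[:, None, None]
        drive = (sf * np.abs(rL)[None]) ** p.n
        pool = p.sigma ** p.n + (sf * np.abs(delayed)[None]) ** p.n
    r = p.scale * _apply_shift(drive / pool, p.shift, fs)
    if not np.all(np.isfinite(r)):
        raise FloatingPointError(f"non-finite DN output for parameters {p}")
    return r
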