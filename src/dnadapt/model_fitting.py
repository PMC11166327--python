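"""Bounded nonlinear least-squares fitting of the DN / csDN models.

Models are fitted per electrode to its 72 trial-averaged condition time
courses (12 temporal conditions x 6 categories) by
``scipy.optimize.least_squares`` with box bounds, multi-start (jittered
starting points, best SSE kept).  Accuracy is quantified by a 12-fold
category-balanced cross-validation: within each fold every category
contributes exactly one held-out condition, training uses the remaining
66 conditions, and the cross-validated coefficient of determination pools
the held-out residuals across folds.  Reported parameters come from a
separate fit to all 72 conditions.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
from scipy.optimize import least_squares

from .trial_design import (CATEGORIES, TemporalCondition,
                           make_stimulus_timecourse, temporal_conditions)
from .dn_model import CategoryScaling, DNParams, dn_forward_batch

__all__ = [
    "ConditionKey", "ConditionResponseSet", "FitConfig", "FitResult",
    "make_folds", "fit_electrode", "coefficient_of_determination",
    "DEFAULT_BOUNDS", "DEFAULT_STARTS",
]

#: (kind, level, category) identifying one of the 72 conditions.
ConditionKey = tuple[str, int, str]

N_CONDITIONS = 72
N_FOLDS = 12

# Bounds and starting points span the physiological regime of fitted
# broadband responses; all configurable through FitConfig.
DEFAULT_BOUNDS: dict[str, tuple[float, float]] = {
    "tau1": (0.005, 1.0),
    "tau2": (0.005, 2.0),
    "n": (0.1, 6.0),
    "sigma": (0.01, 10.0),
    "shift": (0.0, 0.1),
    "scale": (0.01, 200.0),
    "sf": (0.0, 10.0),
}
DEFAULT_STARTS: dict[str, float] = {
    "tau1": 0.05, "tau2": 0.1, "n": 1.5, "sigma": 0.1,
    "shift": 0.03, "scale": 2.0, "sf": 1.0,
}

_DN_NAMES = ("tau1", "tau2", "n", "sigma", "shift", "scale")


def condition_keys() -> list[ConditionKey]:
    """The 72 keys in canonical order (12 conditions x 6 categories)."""
    return [(c.kind, c.level, cat)
            for cat in CATEGORIES for c in temporal_conditions()]


@dataclass
class ConditionResponseSet:
    """An electrode's 72 trial-averaged response time courses.

    ``onset_s`` is the stimulus onset measured from the start of the
    epoch (i.e. 0.1 for a -0.1..1.5 s epoch); all vectors share ``fs``
    and length.
    """

    fs: float
    onset_s: float
    responses: Mapping[ConditionKey, np.ndarray]
    electrode_id: str = "e0"
    area: Optional[str] = None

    def __post_init__(self) -> None:
        keys = set(self.responses)
        expected = set(condition_keys())
        if keys != expected:
            raise ValueError(
                f"expected the 72 canonical condition keys, got "
                f"{len(keys)} keys ({len(keys - expected)} unexpected)")
        lengths = {len(v) for v in self.responses.values()}
        if len(lengths) != 1:
            raise ValueError(f"unequal time-course lengths: {sorted(lengths)}")

    @property
    def n_samples(self) -> int:
        return len(next(iter(self.responses.values())))

    @property
    def epoch_len_s(self) -> float:
        return self.n_samples / self.fs

    def as_array(self) -> np.ndarray:
        """(6 categories, 12 conditions, T) in canonical order."""
        conds = temporal_conditions()
        return np.stack([
            np.stack([np.asarray(self.responses[(c.kind, c.level, cat)])
                      for c in conds])
            for cat in CATEGORIES])


@dataclass
class FitConfig:
    model: str = "csdn"                      # "dn" | "csdn"
    bounds: dict = field(default_factory=lambda: dict(DEFAULT_BOUNDS))
    starts: dict = field(default_factory=lambda: dict(DEFAULT_STARTS))
    n_starts: int = 3
    n_folds: int = N_FOLDS
    max_nfev: int = 2000
    seed: int = 0
    xtol: float = 1e-8
    ftol: float = 1e-8

    def __post_init__(self) -> None:
        if self.model not in ("dn", "csdn"):
            raise ValueError(f"model must be 'dn' or 'csdn', got {self.model!r}")
        for name, (lo, hi) in self.bounds.items():
            if not np.isfinite([lo, hi]).all():
                raise ValueError(f"bounds for {name} must be finite")
            s = self.starts[name]
            if not lo <= s <= hi:
                raise ValueError(f"start {s} for {name} outside [{lo}, {hi}]")

    @property
    def param_names(self) -> list[str]:
        names = list(_DN_NAMES)
        if self.model == "csdn":
            names += [f"sf_{c}" for c in CATEGORIES]
        return names

    def bounds_arrays(self) -> tuple[np.ndarray, np.ndarray]:
        lo, hi = [], []
        for name in self.param_names:
            key = "sf" if name.startswith("sf_") else name
            b = self.bounds[key]
            lo.append(b[0])
            hi.append(b[1])
        return np.array(lo), np.array(hi)

    def start_vector(self) -> np.ndarray:
        return np.array([self.starts["sf" if n.startswith("sf_") else n]
                         for n in self.param_names])


@dataclass
class FitResult:
    params: DNParams
    scalings: Optional[CategoryScaling]
    r2_cv: float
    per_fold_r2: list[float]
    converged: bool
    sse: float
    model: str
    fold_seed: int

    def to_dict(self) -> dict:
        d = {"model": self.model, "r2_cv": self.r2_cv,
             "per_fold_r2": list(self.per_fold_r2),
             "converged": self.converged, "sse": self.sse,
             "fold_seed": self.fold_seed, **self.params.to_dict()}
        if self.scalings is not None:
            d.update({f"sf_{c}": self.scalings[c] for c in CATEGORIES})
        return d

    def save(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def make_folds(keys: Sequence[ConditionKey], seed: int) -> list[set[ConditionKey]]:
    """12 category-balanced cross-validation folds.

    For each category independently, its 12 temporal conditions are
    randomly permuted across the 12 folds, so every fold tests exactly
    one condition per category (6 test keys, 66 training keys).
    """
    keys = list(keys)
    if sorted(keys) != sorted(condition_keys()):
        raise ValueError("keys must be the 72 canonical condition keys")
    rng = np.random.default_rng(seed)
    by_cat: dict[str, list[ConditionKey]] = {c: [] for c in CATEGORIES}
    for k in keys:
        by_cat[k[2]].append(k)
    folds: list[set[ConditionKey]] = [set() for _ in range(N_FOLDS)]
    for cat in CATEGORIES:
        perm = rng.permutation(N_FOLDS)
        cat_keys = sorted(by_cat[cat])
        for fold_idx, key_idx in enumerate(perm):
            folds[fold_idx].add(cat_keys[key_idx])
    return folds


def coefficient_of_determination(pred: np.ndarray, obs: np.ndarray) -> float:
    """R^2 = 1 - SS_res / SS_tot, SS_tot about the observed mean."""
    pred = np.asarray(pred, dtype=float).ravel()
    obs = np.asarray(obs, dtype=float).ravel()
    if pred.shape != obs.shape or obs.size < 2:
        raise ValueError("pred and obs must be equal-length vectors (n >= 2)")
    ss_tot = np.sum((obs - obs.mean()) ** 2)
    if ss_tot == 0:
        raise ValueError("observations are constant; R^2 undefined")
    return float(1.0 - np.sum((obs - pred) ** 2) / ss_tot)


class _Predictor:
    """Caches the 12 base stimulus time courses for fast batched residuals."""

    def __init__(self, data: ConditionResponseSet, cfg: FitConfig):
        self.fs = data.fs
        self.cfg = cfg
        T = data.n_samples
        stims = []
        for cond in temporal_conditions():
            stc = make_stimulus_timecourse(cond, data.fs,
                                           epoch_len_s=data.epoch_len_s,
                                           onset_s=data.onset_s)
            stims.append(stc.values[:T])
        self.stim12 = np.stack(stims)        # (12, T)
        self.obs = data.as_array()           # (6, 12, T)

    def predict(self, theta: np.ndarray) -> np.ndarray:
        p = DNParams(*theta[:6])
        sf = theta[6:12] if self.cfg.model == "csdn" else np.ones(6)
        return dn_forward_batch(self.stim12, self.fs, p, sf)  # (6, 12, T)

    def mask(self, train_keys: set[ConditionKey]) -> np.ndarray:
        conds = temporal_conditions()
        m = np.zeros((len(CATEGORIES), len(conds)), dtype=bool)
        for i, cat in enumerate(CATEGORIES):
            for j, c in enumerate(conds):
                m[i, j] = (c.kind, c.level, cat) in train_keys
        return m


def _fit_once(pred: _Predictor, mask2d: np.ndarray, x0: np.ndarray,
              cfg: FitConfig):
    lo, hi = cfg.bounds_arrays()

    def residuals(theta):
        r = pred.predict(theta)
        return (r[mask2d] - pred.obs[mask2d]).ravel()

    return least_squares(residuals, x0, bounds=(lo, hi), method="trf",
                         max_nfev=cfg.max_nfev, xtol=cfg.xtol, ftol=cfg.ftol,
                         x_scale="jac")


def _jittered_starts(cfg: FitConfig, rng: np.random.Generator) -> list[np.ndarray]:
    lo, hi = cfg.bounds_arrays()
    x0 = cfg.start_vector()
    starts = [x0]
    for _ in range(cfg.n_starts - 1):
        jit = x0 * rng.uniform(0.5, 1.5, size=x0.size)
        jit += rng.uniform(0.0, 0.02, size=x0.size) * (x0 == 0)
        starts.append(np.clip(jit, lo, hi))
    return starts


def fit_electrode(data: ConditionResponseSet, cfg: Optional[FitConfig] = None,
                  compute_cv: bool = True) -> FitResult:
    """Fit DN or csDN to an electrode's 72 condition responses.

    Multi-start bounded least squares on the full dataset gives the
    reported parameters; cross-validation folds are then fitted once
    each, warm-started from the full-dataset solution, and the
    cross-validated R^2 pools held-out residuals across folds.
    """
    cfg = cfg or FitConfig()
    obs_all = np.concatenate([np.asarray(v, dtype=float).ravel()
                              for v in data.responses.values()])
    if not np.any(obs_all):
        raise ValueError(f"electrode {data.electrode_id}: all-zero data, "
                         "gain is undefined")
    pred = _Predictor(data, cfg)
    rng = np.random.default_rng(cfg.seed)
    all_keys = set(condition_keys())
    full_mask = pred.mask(all_keys)

    best = None
    converged = True
    for x0 in _jittered_starts(cfg, rng):
        res = _fit_once(pred, full_mask, x0, cfg)
        if best is None or res.cost < best.cost:
            best = res
    converged = best.status > 0

    per_fold_r2: list[float] = []
    r2_cv = np.nan
    if compute_cv:
        folds = make_folds(list(all_keys), cfg.seed)
        held_pred, held_obs = [], []
        for test_keys in folds:
            train_mask = pred.mask(all_keys - test_keys)
            res = _fit_once(pred, train_mask, best.x, cfg)
            converged = converged and res.status > 0
            test_mask = pred.mask(test_keys)
            p_test = pred.predict(res.x)[test_mask].ravel()
            o_test = pred.obs[test_mask].ravel()
            per_fold_r2.append(coefficient_of_determination(p_test, o_test))
            held_pred.append(p_test)
            held_obs.append(o_test)
        r2_cv = coefficient_of_determination(np.concatenate(held_pred),
                                             np.concatenate(held_obs))

    params = DNParams(*best.x[:6])
    scalings = (CategoryScaling.from_vector(best.x[6:12])
                if cfg.model == "csdn" else None)
    return FitResult(params=params, scalings=scalings, r2_cv=float(r2_cv),
                     per_fold_r2=per_fold_r2, converged=bool(converged),
                     sse=float(2 * best.cost), model=cfg.model,
                     fold_seed=cfg.seed)


def gauge_normalized(params: DNParams, scalings: CategoryScaling
                     ) -> tuple[DNParams, CategoryScaling]:
    """Fix the csDN gauge: rescale so that mean(sf) = 1.

    The csDN prediction is exactly invariant under (sf, sigma) ->
    (alpha*sf, alpha*sigma); comparisons of sigma or sf across fits are
    only meaningful after fixing this gauge.
    """
    g = float(np.mean(scalings.as_vector()))
    if g <= 0:
        raise ValueError("mean scaling factor must be positive")
    p = DNParams(params.tau1, params.tau2, params.n, params.sigma / g,
                 params.shift, params.scale)
    cs = CategoryScaling.from_vector(scalings.as_vector() / g)
    return p, cs
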