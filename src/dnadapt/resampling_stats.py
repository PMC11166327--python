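"""Bootstrap-over-electrodes summaries and sign-test inference.

Group summaries resample k electrodes with replacement, average their
time courses pointwise, and evaluate a summary metric on each averaged
time course; the bootstrap distribution is summarized by its median and
68% confidence interval (16th/84th percentiles).  Two bootstrap
distributions are compared with a paired sign test: the smaller of the
positive/negative difference counts divided by the number of draws,
declared significant below alpha (0.025 two-tailed by convention,
Bonferroni-divided across pairwise comparisons).

This sign test on bootstrap draws is anticonservative relative to an
exact test on independent observations -- the draws are resampled, not
independent.  It is implemented literally as specified and documented as
such; the calibration property test only bounds its false-positive rate
loosely.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Optional, Sequence

import numpy as np

__all__ = ["BootstrapDistribution", "SignTestResult",
           "bootstrap_metric", "sign_test", "bonferroni_alpha",
           "percentile_ci"]


@dataclass
class BootstrapDistribution:
    samples: np.ndarray          # metric values; NaN marks a missing draw
    median: float
    ci68: tuple[float, float]
    n: int                       # number of draws
    k: int                       # electrodes per draw
    seed: int
    n_missing: int = 0

    def to_dict(self) -> dict:
        return {"median": self.median, "ci68": list(self.ci68), "n": self.n,
                "k": self.k, "seed": self.seed, "n_missing": self.n_missing}


@dataclass
class SignTestResult:
    p: float
    alpha: float
    n: int
    significant: bool

    def to_dict(self) -> dict:
        return {"p": self.p, "alpha": self.alpha, "n": self.n,
                "significant": self.significant}


def percentile_ci(samples: np.ndarray, coverage: float = 0.68
                  ) -> tuple[float, float]:
    """Empirical central interval at the given coverage."""
    if not 0 < coverage < 1:
        raise ValueError("coverage must be in (0, 1)")
    lo = 50.0 * (1.0 - coverage)
    return (float(np.percentile(samples, lo)),
            float(np.percentile(samples, 100.0 - lo)))


def bootstrap_metric(tcs: Sequence[np.ndarray],
                     metric: Callable[[np.ndarray], float],
                     n: int = 1000, seed: int = 0,
                     k: Optional[int] = None,
                     max_missing_frac: float = 0.2) -> BootstrapDistribution:
    """Bootstrap a summary metric over electrodes.

    Each of ``n`` draws samples ``k`` electrodes with replacement (k
    defaults to the number of electrodes), averages their time courses
    pointwise and applies ``metric`` to the average.  Draws on which the
    metric is undefined (raises or returns NaN) are recorded as missing;
    more than ``max_missing_frac`` missing draws is an error.
    """
    stack = np.stack([np.asarray(t, dtype=float) for t in tcs])
    m = stack.shape[0]
    if m < 1:
        raise ValueError("at least one electrode is required")
    if k is None:
        k = m
    rng = np.random.default_rng(seed)
    samples = np.full(n, np.nan)
    for i in range(n):
        idx = rng.integers(0, m, size=k)
        avg = stack[idx].mean(axis=0)
        try:
            samples[i] = metric(avg)
        except (ValueError, FloatingPointError):
            pass   # missing draw
    valid = samples[np.isfinite(samples)]
    n_missing = n - valid.size
    if n_missing > max_missing_frac * n:
        raise ValueError(
            f"metric undefined on {n_missing}/{n} bootstrap draws "
            f"(> {max_missing_frac:.0%} allowed)")
    return BootstrapDistribution(
        samples=samples, median=float(np.median(valid)),
        ci68=percentile_ci(valid, 0.68), n=n, k=k, seed=seed,
        n_missing=n_missing)


def sign_test(dist_a: np.ndarray, dist_b: np.ndarray,
              alpha: float = 0.025) -> SignTestResult:
    """Paired sign test on bootstrap draws.

    p = min(#{a-b > 0}, #{a-b < 0}) / n.  Zero differences count toward
    n but toward neither tally.
    """
    a = np.asarray(dist_a, dtype=float)
    b = np.asarray(dist_b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("distributions must be equal-length 1-d arrays")
    n = a.size
    if n == 0:
        raise ValueError("empty distributions")
    d = a - b
    p = float(min(np.sum(d > 0), np.sum(d < 0)) / n)
    return SignTestResult(p=p, alpha=alpha, n=n, significant=p < alpha)


def bonferroni_alpha(base_alpha: float, m: int) -> float:
    """Bonferroni-corrected level base_alpha / m."""
    if m < 1:
        raise ValueError("number of comparisons must be >= 1")
    return base_alpha / m
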