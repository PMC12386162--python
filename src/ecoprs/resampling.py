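"""Bootstrap and permutation inference for the ecological correlation.

With five populations the sampling distribution of r is wildly unstable, so
parametric p-values and CIs are backed up by resampling:

* ``bootstrap_ci`` resamples (PRS, prevalence) pairs with replacement and
  builds a percentile or BCa interval. At n = 5 many resamples collapse to
  fewer than two distinct x or y values, where r is undefined; such
  degenerate resamples are either excluded from the empirical distribution
  (default, with their count reported) or redrawn.
* ``permutation_test`` breaks the pairing by permuting y. For n <= 8 every
  pairing is enumerated and the p-value is exact (k / n!, identity
  included); otherwise random permutations are drawn and the add-one
  estimator (1 + k) / (n_perm + 1) keeps p away from zero.

BCa details: the bias correction is z0 = Phi^-1(F(r_obs)) where F is the
empirical CDF of valid resample correlations (ties with the observed value
count half); the acceleration a comes from the jackknife skewness of the
leave-one-out estimates; the adjusted percentile endpoints are clamped to
[-1, 1].
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from itertools import permutations as _permutations

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, DomainError, InferenceError, ValidationError

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class BootstrapResult:
    n_iter: int
    observed_r: float
    ci_low: float
    ci_high: float
    conf: float
    method: str  # 'bca' | 'percentile'
    z0: float
    a: float
    n_degenerate: int
    fraction_positive: float
    degenerate_policy: str
    seed: int


@dataclass(frozen=True)
class PermutationResult:
    mode: str  # 'exact' | 'monte_carlo'
    n_perm: int
    observed_r: float
    p: float
    seed: int | None


def _validate_pair(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or len(x) != len(y):
        raise ValidationError("x and y must be 1-D vectors of equal length")
    if len(x) < min_n:
        raise ValidationError(f"need at least {min_n} observations")
    if np.ptp(x) == 0.0 or np.ptp(y) == 0.0:
        raise DegenerateInputError("constant vector; correlation undefined")
    return x, y


def _pearson_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = np.sum(Xc * Yc, axis=1)
    den = np.sqrt(np.sum(Xc**2, axis=1) * np.sum(Yc**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def bca_quantile_levels(z0: float, a: float, conf: float) -> tuple[float, float]:
    """BCa-adjusted quantile levels; reduces to (alpha/2, 1-alpha/2) when
    z0 = a = 0."""
    alpha = 1.0 - conf
    out = []
    for q in (alpha / 2.0, 1.0 - alpha / 2.0):
        zq = stats.norm.ppf(q)
        adj = z0 + (z0 + zq) / (1.0 - a * (z0 + zq))
        out.append(float(stats.norm.cdf(adj)))
    return out[0], out[1]


def bootstrap_ci(
    x,
    y,
    n_iter: int = 10_000,
    method: str = "bca",
    conf: float = 0.95,
    seed: int | None = None,
    degenerate_policy: str = "exclude",
) -> BootstrapResult:
    """Bootstrap CI for Pearson's r by resampling (x, y) pairs.

    One seeded generator drives the whole call; each iteration draws n
    independent uniform pair indices with replacement.
    """
    x, y = _validate_pair(x, y)
    if not 0.0 < conf < 1.0:
        raise DomainError("conf must be in (0, 1)")
    if n_iter < 100:
        raise ValidationError("n_iter must be at least 100")
    if method not in ("bca", "percentile"):
        raise ValidationError(f"unknown bootstrap method {method!r}")
    if degenerate_policy not in ("exclude", "redraw"):
        raise ValidationError(f"unknown degenerate policy {degenerate_policy!r}")
    if seed is None:
        raise ValidationError("bootstrap_ci requires an explicit seed")

    n = len(x)
    rng = np.random.default_rng(seed)
    observed = float(stats.pearsonr(x, y).statistic)

    idx = rng.integers(0, n, size=(n_iter, n))
    r_star = _pearson_rows(x[idx], y[idx])
    valid = np.isfinite(r_star)
    n_degenerate = int(np.sum(~valid))
    if degenerate_policy == "exclude":
        r_star = r_star[valid]
    else:  # redraw until every slot holds a valid resample
        guard = 0
        while not valid.all():
            bad = np.flatnonzero(~valid)
            idx_new = rng.integers(0, n, size=(len(bad), n))
            r_new = _pearson_rows(x[idx_new], y[idx_new])
            r_star[bad] = r_new
            valid = np.isfinite(r_star)
            guard += 1
            if guard > 10_000:
                raise InferenceError("could not redraw non-degenerate resamples")
    if r_star.size == 0:
        raise InferenceError("all bootstrap resamples were degenerate")

    fraction_positive = float(np.mean(r_star > 0.0))

    if method == "bca":
        below = np.sum(r_star < observed - _TIE_TOL)
        ties = np.sum(np.abs(r_star - observed) <= _TIE_TOL)
        frac = (below + 0.5 * ties) / r_star.size
        frac = min(max(frac, 1.0 / (r_star.size + 1)), 1.0 - 1.0 / (r_star.size + 1))
        z0 = float(stats.norm.ppf(frac))
        theta = np.array(
            [
                float(stats.pearsonr(np.delete(x, i), np.delete(y, i)).statistic)
                for i in range(n)
            ]
        )
        d = theta.mean() - theta
        denom = 6.0 * np.sum(d**2) ** 1.5
        a = float(np.sum(d**3) / denom) if denom > 0 else 0.0
        lo_q, hi_q = bca_quantile_levels(z0, a, conf)
    else:
        z0, a = 0.0, 0.0
        alpha = 1.0 - conf
        lo_q, hi_q = alpha / 2.0, 1.0 - alpha / 2.0

    ci_low, ci_high = np.quantile(r_star, [lo_q, hi_q])
    return BootstrapResult(
        n_iter=n_iter,
        observed_r=observed,
        ci_low=float(max(ci_low, -1.0)),
        ci_high=float(min(ci_high, 1.0)),
        conf=conf,
        method=method,
        z0=z0,
        a=a,
        n_degenerate=n_degenerate,
        fraction_positive=fraction_positive,
        degenerate_policy=degenerate_policy,
        seed=seed,
    )


def permutation_test(
    x,
    y,
    n_perm: int = 10_000,
    seed: int | None = None,
    exact_threshold: int = 40_320,
) -> PermutationResult:
    """Two-sided permutation test of Pearson's r.

    Exact mode (n! <= exact_threshold) enumerates every pairing of y
    against x and reports p = #{|r_pi| >= |r_obs|} / n!, identity included,
    so 1/n! <= p <= 1. Monte-Carlo mode draws ``n_perm`` random pairings and
    reports (1 + k) / (n_perm + 1); it requires an explicit seed.
    """
    x, y = _validate_pair(x, y)
    n = len(x)
    observed = float(stats.pearsonr(x, y).statistic)
    threshold = abs(observed) - _TIE_TOL

    if math.factorial(n) <= exact_threshold:
        perm_idx = np.array(list(_permutations(range(n))), dtype=int)
        r_pi = _pearson_rows(x[np.newaxis, :], y[perm_idx])
        k = int(np.sum(np.abs(r_pi) >= threshold))
        return PermutationResult(
            mode="exact",
            n_perm=len(perm_idx),
            observed_r=observed,
            p=k / len(perm_idx),
            seed=None,
        )

    if seed is None:
        raise ValidationError("Monte-Carlo permutation requires an explicit seed")
    if n_perm < 1:
        raise ValidationError("n_perm must be positive")
    rng = np.random.default_rng(seed)
    perms = np.array([rng.permutation(n) for _ in range(n_perm)])
    r_pi = _pearson_rows(x[np.newaxis, :], y[perms])
    k = int(np.sum(np.abs(r_pi) >= threshold))
    return PermutationResult(
        mode="monte_carlo",
        n_perm=n_perm,
        observed_r=observed,
        p=(1 + k) / (n_perm + 1),
        seed=seed,
    )


def monte_carlo_permutation(
    x, y, n_perm: int = 10_000, seed: int | None = None
) -> PermutationResult:
    """Force Monte-Carlo mode regardless of n (exact enumeration disabled)."""
    return permutation_test(x, y, n_perm=n_perm, seed=seed, exact_threshold=0)
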