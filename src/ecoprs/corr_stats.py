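"""Ecological correlation statistics for PRS vs prevalence.

The unit of observation is a population, so n is tiny (five in the worked
example) and every result here must be read as ecological: a cross-population
correlation says nothing about individual-level risk. The module provides

* Pearson's r with the exact t-test (df = n-2) and a Fisher-z confidence
  interval,
* Spearman's rank correlation with an exact permutation p at small n,
* leave-one-out sensitivity (how much a single population drives r),
* post-hoc power and required sample size from the Fisher-z approximation:

      C = 0.5 * ln[(1+|r|)/(1-|r|)]
      power = Phi(C * sqrt(n-3) - z_{alpha/2})
      n_required = ceil[ (z_{alpha/2} + z_beta)^2 / C^2 + 3 ]

Two analysis presets exist because rounding the PRS vector to 3 decimals
before correlating changes r at n = 5 (full precision: r = -0.407; rounded:
r = -0.396 on the packaged example); ``prs_rounding`` records which was used.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from itertools import permutations

import numpy as np
from scipy import stats

from .errors import DegenerateInputError, DomainError, ValidationError

_TIE_TOL = 1e-12


@dataclass(frozen=True)
class CorrelationResult:
    method: str  # 'pearson' | 'spearman'
    transform: str  # 'raw' | 'log'
    prs_rounding: str  # 'none' | '3dp'
    r: float
    n: int
    t: float
    df: int
    p: float
    r_squared: float
    ci_low: float | None
    ci_high: float | None
    degenerate: bool = False  # |r| = 1, p reported as exact 0
    ci_omitted: bool = False  # n too small for a Fisher-z interval


@dataclass(frozen=True)
class LeaveOneOutEntry:
    excluded: str
    r: float
    p: float
    direction_changed: bool


@dataclass(frozen=True)
class LeaveOneOutResult:
    full_r: float
    entries: tuple[LeaveOneOutEntry, ...]


@dataclass(frozen=True)
class PowerResult:
    r_magnitude: float
    C: float
    z_alpha: float
    z_beta: float | None
    n: int | None
    power: float | None
    required_n: int | None


# ---------------------------------------------------------------------------
# correlation
# ---------------------------------------------------------------------------

def _as_vectors(x, y, min_n: int = 3) -> tuple[np.ndarray, np.ndarray]:
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.ndim != 1 or y.ndim != 1 or len(x) != len(y):
        raise ValidationError("x and y must be 1-D vectors of equal length")
    if len(x) < min_n:
        raise ValidationError(f"need at least {min_n} observations, got {len(x)}")
    if np.ptp(x) == 0.0:
        raise DegenerateInputError("x is constant; correlation undefined")
    if np.ptp(y) == 0.0:
        raise DegenerateInputError("y is constant; correlation undefined")
    return x, y


def pearson(x, y) -> float:
    """Product-moment correlation at full precision."""
    x, y = _as_vectors(x, y)
    return float(stats.pearsonr(x, y).statistic)


def pearson_test(
    x,
    y,
    transform: str = "raw",
    prs_rounding: str = "none",
    conf: float = 0.95,
) -> CorrelationResult:
    """Pearson correlation with t-test and Fisher-z CI.

    ``x`` is the PRS vector and ``y`` the prevalence vector. ``transform``
    applies the natural log to ``y`` (requires positive values);
    ``prs_rounding='3dp'`` rounds ``x`` to 3 decimals before correlating
    (the t statistic and p then use the resulting r, not a re-rounded one).
    """
    if transform not in ("raw", "log"):
        raise ValidationError(f"unknown transform {transform!r}")
    if prs_rounding not in ("none", "3dp"):
        raise ValidationError(f"unknown prs_rounding {prs_rounding!r}")
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if transform == "log":
        if np.any(y <= 0):
            raise DomainError("log transform requires strictly positive y")
        y = np.log(y)
    if prs_rounding == "3dp":
        x = np.round(x, 3)
    x, y = _as_vectors(x, y)
    r = float(stats.pearsonr(x, y).statistic)
    return _finish_test(r, len(x), "pearson", transform, prs_rounding, conf)


def _finish_test(
    r: float, n: int, method: str, transform: str, prs_rounding: str, conf: float
) -> CorrelationResult:
    df = n - 2
    degenerate = bool(abs(r) >= 1.0 - _TIE_TOL)
    if degenerate:
        t = math.copysign(math.inf, r)
        p = 0.0
    else:
        t = r * math.sqrt(df) / math.sqrt(1.0 - r * r)
        p = float(2.0 * stats.t.sf(abs(t), df))
    ci_low = ci_high = None
    ci_omitted = n < 4 or degenerate
    if not ci_omitted:
        z = math.atanh(r)
        half = stats.norm.ppf(0.5 + conf / 2.0) / math.sqrt(n - 3)
        ci_low = float(math.tanh(z - half))
        ci_high = float(math.tanh(z + half))
    return CorrelationResult(
        method=method,
        transform=transform,
        prs_rounding=prs_rounding,
        r=r,
        n=n,
        t=float(t),
        df=df,
        p=p,
        r_squared=r * r,
        ci_low=ci_low,
        ci_high=ci_high,
        degenerate=degenerate,
        ci_omitted=ci_omitted,
    )


def spearman(x, y, exact_threshold: int = 40320) -> CorrelationResult:
    """Rank correlation; ties get average ranks.

    rho is Pearson's r applied to the rank vectors (identical to the
    1 - 6*sum(d^2)/[n(n^2-1)] formula when no ties are present). The
    two-sided p comes from exact enumeration of all rank pairings when
    n! <= exact_threshold, otherwise from the t approximation.
    """
    x, y = _as_vectors(x, y)
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    rho = float(stats.pearsonr(rx, ry).statistic)
    n = len(x)
    result = _finish_test(rho, n, "spearman", "raw", "none", 0.95)
    if math.factorial(n) <= exact_threshold:
        perm_idx = np.array(list(permutations(range(n))), dtype=int)
        rp = _pearson_rows(rx[np.newaxis, :], ry[perm_idx])
        count = int(np.sum(np.abs(rp) >= abs(rho) - _TIE_TOL))
        result = replace(result, p=count / len(perm_idx))
    return result


def _pearson_rows(X: np.ndarray, Y: np.ndarray) -> np.ndarray:
    """Row-wise Pearson correlation of broadcastable 2-D arrays."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    num = np.sum(Xc * Yc, axis=1)
    den = np.sqrt(np.sum(Xc**2, axis=1) * np.sum(Yc**2, axis=1))
    with np.errstate(invalid="ignore", divide="ignore"):
        return num / den


def leave_one_out(x, y, labels, transform: str = "raw",
                  prs_rounding: str = "none") -> LeaveOneOutResult:
    """Recompute the correlation excluding each observation in turn."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    labels = list(labels)
    if len(labels) != len(x):
        raise ValidationError("labels must match the data length")
    if len(x) < 4:
        raise ValidationError("leave-one-out needs at least 4 observations")
    full = pearson_test(x, y, transform=transform, prs_rounding=prs_rounding)
    entries = []
    for i, label in enumerate(labels):
        sub = pearson_test(
            np.delete(x, i), np.delete(y, i),
            transform=transform, prs_rounding=prs_rounding,
        )
        entries.append(
            LeaveOneOutEntry(
                excluded=label,
                r=sub.r,
                p=sub.p,
                direction_changed=bool(math.copysign(1, sub.r) != math.copysign(1, full.r)),
            )
        )
    return LeaveOneOutResult(full_r=full.r, entries=tuple(entries))


# ---------------------------------------------------------------------------
# power analysis
# ---------------------------------------------------------------------------

def _fisher_c(r: float) -> float:
    r = abs(float(r))
    if not 0.0 < r < 1.0:
        raise DomainError(f"|r| must be strictly inside (0, 1), got {r}")
    return 0.5 * math.log((1.0 + r) / (1.0 - r))


def posthoc_power(r: float, n: int, alpha: float = 0.05) -> PowerResult:
    """Achieved power of the two-sided correlation test at effect size |r|."""
    if n < 4:
        raise DomainError("power formula needs n >= 4")
    if not 0.0 < alpha < 1.0:
        raise DomainError("alpha must be in (0, 1)")
    C = _fisher_c(r)
    z_alpha = float(stats.norm.ppf(1.0 - alpha / 2.0))
    power = float(stats.norm.cdf(C * math.sqrt(n - 3) - z_alpha))
    return PowerResult(
        r_magnitude=abs(float(r)),
        C=C,
        z_alpha=z_alpha,
        z_beta=None,
        n=n,
        power=power,
        required_n=None,
    )


def required_n(r: float, alpha: float = 0.05, beta: float = 0.20) -> int:
    """Smallest sample size giving power 1-beta for effect size |r|,
    via ceil[(z_{alpha/2} + z_beta)^2 / C^2 + 3]."""
    if not 0.0 < alpha < 1.0 or not 0.0 < beta < 1.0:
        raise DomainError("alpha and beta must be in (0, 1)")
    C = _fisher_c(r)
    z_alpha = float(stats.norm.ppf(1.0 - alpha / 2.0))
    z_beta = float(stats.norm.ppf(1.0 - beta))
    n = math.ceil((z_alpha + z_beta) ** 2 / C**2 + 3.0)
    return max(n, 4)


def power_analysis(r: float, n: int, alpha: float = 0.05,
                   beta: float = 0.20) -> PowerResult:
    """Achieved power at the observed n plus the n required for 1-beta power."""
    achieved = posthoc_power(r, n, alpha=alpha)
    return PowerResult(
        r_magnitude=achieved.r_magnitude,
        C=achieved.C,
        z_alpha=achieved.z_alpha,
        z_beta=float(stats.norm.ppf(1.0 - beta)),
        n=n,
        power=achieved.power,
        required_n=required_n(r, alpha=alpha, beta=beta),
    )
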