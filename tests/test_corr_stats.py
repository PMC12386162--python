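"""Correlation, leave-one-out sensitivity and Fisher-z power analysis."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from ecoprs import (
    DegenerateInputError,
    DomainError,
    ValidationError,
    leave_one_out,
    pearson,
    pearson_test,
    posthoc_power,
    power_analysis,
    required_n,
    spearman,
)

# ---------------------------------------------------------------------------
# pearson
# ---------------------------------------------------------------------------


def test_full_precision_correlation_reproduces_published(prs_prevalence_vectors):
    x, y, _ = prs_prevalence_vectors
    assert round(pearson(x, y), 3) == -0.407
    result = pearson_test(x, y)
    assert round(result.p, 3) == 0.496
    assert round(result.r_squared, 3) == 0.166
    assert result.df == 3
    assert result.ci_low <= result.r <= result.ci_high


def test_rounded_prs_preset_reproduces_published(prs_prevalence_vectors):
    x, y, _ = prs_prevalence_vectors
    result = pearson_test(x, y, prs_rounding="3dp")
    assert round(result.r, 3) == -0.396
    assert round(result.p, 3) == 0.510


def test_pearson_exact_affine_cases():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    assert pearson(x, x) == pytest.approx(1.0)
    assert pearson(x, 3.0 - 2.0 * x) == pytest.approx(-1.0)


def test_constant_vector_is_a_loud_error():
    x = np.array([1.0, 2.0, 3.0])
    with pytest.raises(DegenerateInputError):
        pearson(x, np.ones(3))
    with pytest.raises(DegenerateInputError):
        pearson(np.ones(3), x)


def test_log_transform_requires_positive_y():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    with pytest.raises(DomainError):
        pearson_test(x, np.array([1.0, -1.0, 2.0, 3.0]), transform="log")


def test_perfect_correlation_flagged_degenerate():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    result = pearson_test(x, 2 * x)
    assert result.degenerate
    assert result.p == 0.0


def test_small_n_omits_ci_with_flag():
    result = pearson_test([1.0, 2.0, 4.0], [3.0, 1.0, 2.0])
    assert result.ci_omitted
    assert result.ci_low is None and result.ci_high is None


def test_p_matches_exact_t_tail_for_df_3():
    """The two-sided p equals the closed-form t CDF with 3 degrees of
    freedom: for df=3, P(T > t) = 1/2 - (1/pi)*(arctan(u) + u/(1+u^2)),
    u = t/sqrt(3) — an independent series evaluation."""
    x = np.array([0.1, 0.9, 0.4, 0.7, 0.2])
    y = np.array([5.0, 1.0, 4.0, 2.0, 6.0])
    result = pearson_test(x, y)
    u = abs(result.t) / math.sqrt(3)
    tail = 0.5 - (math.atan(u) + u / (1 + u * u)) / math.pi
    assert result.p == pytest.approx(2 * tail, rel=1e-12)


def test_fisher_ci_closed_form(prs_prevalence_vectors):
    x, y, _ = prs_prevalence_vectors
    result = pearson_test(x, y)
    z = math.atanh(result.r)
    half = stats.norm.ppf(0.975) / math.sqrt(len(x) - 3)
    assert result.ci_low == pytest.approx(math.tanh(z - half), rel=1e-12)
    assert result.ci_high == pytest.approx(math.tanh(z + half), rel=1e-12)


@given(
    x=st.lists(st.floats(-100, 100), min_size=4, max_size=12, unique=True),
    a=st.floats(0.1, 10), b=st.floats(-50, 50),
    c=st.floats(0.1, 10), d=st.floats(-50, 50),
)
@settings(max_examples=100, deadline=None)
def test_pearson_affine_invariance_and_antisymmetry(x, a, b, c, d):
    x = np.array(x)
    rng = np.random.default_rng(0)
    y = rng.permutation(x) + rng.normal(0, 1, len(x))
    if np.ptp(y) == 0:
        return
    r = pearson(x, y)
    assert pearson(a * x + b, c * y + d) == pytest.approx(r, abs=1e-8)
    assert pearson(-x, y) == pytest.approx(-r, abs=1e-8)


# ---------------------------------------------------------------------------
# spearman
# ---------------------------------------------------------------------------


def test_spearman_matches_d_squared_formula(prs_prevalence_vectors):
    """rho equals 1 - 6*sum(d^2)/(n(n^2-1)) on the tie-free example data.
    Hand-ranking the five PRS and prevalence values gives rank differences
    d = (3, -3, 2, 1, -3), sum(d^2) = 32, rho = 1 - 192/120 = -0.6."""
    x, y, _ = prs_prevalence_vectors
    rx = stats.rankdata(x)
    ry = stats.rankdata(y)
    d2 = np.sum((rx - ry) ** 2)
    n = len(x)
    expected = 1 - 6 * d2 / (n * (n**2 - 1))
    result = spearman(x, y)
    assert result.r == pytest.approx(expected, rel=1e-12)
    assert result.r == pytest.approx(-0.6, rel=1e-12)
    # exact permutation p over 120 rank pairings
    assert result.p == pytest.approx(42 / 120, rel=1e-12)


def test_spearman_concordant_and_reversed():
    x = np.array([1.0, 2.0, 3.0, 4.0, 5.0])
    assert spearman(x, x**3).r == pytest.approx(1.0)
    assert spearman(x, -np.exp(x)).r == pytest.approx(-1.0)


@given(seed=st.integers(0, 500), n=st.integers(4, 10))
@settings(max_examples=60, deadline=None)
def test_spearman_equals_pearson_on_ranks(seed, n):
    rng = np.random.default_rng(seed)
    x = rng.normal(size=n)
    y = rng.normal(size=n)
    result = spearman(x, y)
    assert result.r == pytest.approx(
        pearson(stats.rankdata(x), stats.rankdata(y)), rel=1e-10
    )


# ---------------------------------------------------------------------------
# leave-one-out
# ---------------------------------------------------------------------------


def test_leave_one_out_matches_direct_recomputation(prs_prevalence_vectors):
    """Each subset r/p equals an independent 4-point Pearson computed with
    scipy on the remaining pairs."""
    x, y, labels = prs_prevalence_vectors
    result = leave_one_out(x, y, labels)
    assert [e.excluded for e in result.entries] == labels
    for i, entry in enumerate(result.entries):
        r_ref, p_ref = stats.pearsonr(np.delete(x, i), np.delete(y, i))
        assert entry.r == pytest.approx(r_ref, rel=1e-12)
        assert entry.p == pytest.approx(p_ref, rel=1e-9)
        assert entry.direction_changed == (np.sign(entry.r) != np.sign(result.full_r))


def test_leave_one_out_on_point_on_regression_line():
    # the fifth point lies exactly on the line through the others: removing
    # it cannot flip the sign
    x = np.array([0.0, 1.0, 2.0, 3.0, 1.5])
    y = 2.0 * x + np.array([0.5, -0.5, 0.5, -0.5, 0.0])
    y[4] = 2.0 * x[4]
    result = leave_one_out(x, y, list("abcde"))
    assert not result.entries[4].direction_changed


def test_leave_one_out_collinear_subsets():
    x = np.array([1.0, 2.0, 3.0, 4.0])
    result = leave_one_out(x, -3 * x + 1, list("abcd"))
    for entry in result.entries:
        assert entry.r == pytest.approx(-1.0)


def test_leave_one_out_with_duplicated_point():
    rng = np.random.default_rng(3)
    x = np.array([1.0, 2.0, 3.0, 4.0, 4.0])
    y = np.array([2.0, 1.0, 5.0, 3.0, 3.0])
    result = leave_one_out(x, y, list("abcde"))
    # excluding either copy of the duplicate gives the same subset statistic
    assert result.entries[3].r == pytest.approx(result.entries[4].r, rel=1e-12)


def test_leave_one_out_needs_four_points():
    with pytest.raises(ValidationError):
        leave_one_out([1.0, 2.0, 3.0], [1.0, 3.0, 2.0], list("abc"))


# ---------------------------------------------------------------------------
# power
# ---------------------------------------------------------------------------


def test_posthoc_power_reproduces_published():
    result = posthoc_power(0.396, n=5)
    assert round(100 * result.power, 1) == 8.6
    assert result.C == pytest.approx(0.5 * math.log(1.396 / 0.604), rel=1e-12)


def test_required_n_reproduces_published():
    assert required_n(0.396) == 48


def test_power_is_half_at_the_critical_point():
    # choose n so that C*sqrt(n-3) == z_{alpha/2} exactly
    r = 0.3
    C = 0.5 * math.log((1 + r) / (1 - r))
    z = stats.norm.ppf(0.975)
    n = 3 + (z / C) ** 2
    # non-integer n: evaluate the formula path directly via a nearby alpha
    power = stats.norm.cdf(C * math.sqrt(n - 3) - z)
    assert power == pytest.approx(0.5, abs=1e-12)
    # and the implementation approaches 1 as n grows
    assert posthoc_power(r, n=10_000).power > 0.9999


def test_required_n_floor_for_huge_effects():
    assert required_n(0.999999) == 4


@pytest.mark.parametrize("r", [0.1, 0.2, 0.3, 0.396, 0.5, 0.6, 0.7, 0.8, 0.9])
def test_power_at_required_n_meets_target(r):
    n = required_n(r, alpha=0.05, beta=0.20)
    assert posthoc_power(r, n=n).power >= 0.80


def test_power_monotone_in_n():
    powers = [posthoc_power(0.4, n=n).power for n in range(4, 60)]
    assert all(b > a for a, b in zip(powers, powers[1:]))


@pytest.mark.parametrize("r", [0.0, 1.0])
def test_power_domain_errors(r):
    with pytest.raises(DomainError):
        posthoc_power(r, n=10)
    with pytest.raises(DomainError):
        required_n(r)


def test_power_analysis_combines_both():
    result = power_analysis(0.396, n=5)
    assert result.required_n == 48
    assert round(100 * result.power, 1) == 8.6
    assert result.z_beta == pytest.approx(stats.norm.ppf(0.80), rel=1e-12)
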