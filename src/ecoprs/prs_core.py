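"""Population-level polygenic risk scores and their decomposition.

A population's expected individual score under Hardy-Weinberg diploidy is

    PRS = sum_i 2 * beta_i * f_i

where ``beta_i`` is the per-copy effect weight of variant *i* and ``f_i``
the effect-allele frequency in that population; the factor 2 counts the two
chromosome copies. Each term ``c_i = 2 * beta_i * f_i`` is that variant's
contribution, and the variance of ``c_i`` across populations measures how
much each variant drives cross-population PRS differences.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import DomainError, ValidationError
from .io_formats import FrequencyTable, ScoringModel


@dataclass(frozen=True)
class PopulationPRS:
    """Score and per-variant contributions for one population."""

    population: str
    prs: float
    contributions: tuple[float, ...]  # scoring-model order, c_i = 2*beta_i*f_i

    def __post_init__(self) -> None:
        total = float(np.sum(self.contributions))
        if not np.isclose(self.prs, total, rtol=1e-12, atol=0.0):
            raise ValidationError(
                f"PRS {self.prs!r} for {self.population} does not equal the "
                f"sum of contributions {total!r}"
            )


@dataclass(frozen=True)
class ContributionAnalysis:
    """Across-population variance of each variant's contribution."""

    variants: tuple[str, ...]
    variances: tuple[float, ...]
    convention: str  # 'sample' (/(K-1)) or 'population' (/K)
    ranking: tuple[str, ...]  # variants by descending variance


def population_prs(
    model: ScoringModel, freqs: FrequencyTable, population: str
) -> PopulationPRS:
    """Score one population; inputs must already be harmonized (same variant
    list and order in model and table)."""
    _check_aligned(model, freqs)
    row = freqs.population_row(population)  # raises KeyError when unknown
    contributions = 2.0 * model.weights * row
    return PopulationPRS(
        population=population,
        prs=float(contributions.sum()),
        contributions=tuple(float(c) for c in contributions),
    )


def all_population_prs(
    model: ScoringModel, freqs: FrequencyTable
) -> list[PopulationPRS]:
    """Score every population in the table, preserving table order."""
    return [population_prs(model, freqs, pop) for pop in freqs.populations]


def rank_order(scores: list[PopulationPRS]) -> list[str]:
    """Population codes by descending PRS; ties broken lexicographically."""
    if not scores:
        raise ValidationError("no scores to rank")
    return [s.population for s in sorted(scores, key=lambda s: (-s.prs, s.population))]


def contribution_variance(
    scores: list[PopulationPRS],
    model: ScoringModel,
    convention: str = "sample",
) -> ContributionAnalysis:
    """Variance of each variant's contribution across populations.

    ``convention='sample'`` divides by K-1, ``'population'`` by K. Ranking
    ties are broken by scoring-model order.
    """
    if len(scores) < 2:
        raise ValidationError("contribution variance needs at least 2 populations")
    if convention not in ("sample", "population"):
        raise ValidationError(f"unknown variance convention {convention!r}")
    C = np.array([s.contributions for s in scores], dtype=float)  # (K, M)
    if C.shape[1] != len(model):
        raise ValidationError("scores and model disagree on the variant count")
    ddof = 1 if convention == "sample" else 0
    variances = C.var(axis=0, ddof=ddof)
    labels = tuple(v.label for v in model.variants)
    order = sorted(range(len(labels)), key=lambda j: (-variances[j], j))
    return ContributionAnalysis(
        variants=labels,
        variances=tuple(float(v) for v in variances),
        convention=convention,
        ranking=tuple(labels[j] for j in order),
    )


def fold_difference(
    freqs: FrequencyTable, variant: str, pop_a: str, pop_b: str
) -> float:
    """Ratio f_a / f_b of one variant's effect-allele frequency."""
    fa = freqs.frequency(pop_a, variant)
    fb = freqs.frequency(pop_b, variant)
    if fb == 0.0:
        raise DomainError(
            f"fold difference undefined: {variant} has frequency 0 in {pop_b}"
        )
    if fa == 0.0:
        raise DomainError(
            f"fold difference undefined: {variant} has frequency 0 in {pop_a}"
        )
    return fa / fb


def _check_aligned(model: ScoringModel, freqs: FrequencyTable) -> None:
    model_rsids = tuple(v.rsid for v in model.variants)
    if None in model_rsids or model_rsids != freqs.variants:
        raise ValidationError(
            "scoring model and frequency table are not harmonized "
            "(variant lists differ); run io_formats.harmonize first"
        )
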