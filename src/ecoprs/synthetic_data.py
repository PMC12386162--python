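"""Synthetic scoring models, frequency tables and prevalence data.

The generator emulates the structure of the real inputs so that every
pipeline stage can be exercised and calibrated without downloads:

* Variant weights are drawn uniformly from a positive range; the default
  [0.07, 0.12] brackets the weights of the packaged seven-variant score.
* Per-population effect-allele frequencies follow the Balding-Nichols
  drift model: for ancestral frequency p0 and differentiation F (an FST
  analogue), each population draws

      f ~ Beta(p0 * (1-F)/F, (1-p0) * (1-F)/F)

  which has mean p0 and variance F * p0 * (1-p0). The default F = 0.005
  mimics the weak differentiation between European populations.
* Prevalence is linked to the population PRS through a configurable
  ecological slope b and Gaussian noise sigma, either on the linear scale
  (prevalence = a + b*PRS + eps, truncated below at 1 per 100,000) or on
  the log scale (prevalence = exp(a + b*PRS + eps)). Setting b = 0 yields
  null datasets for calibration studies.

What this does NOT emulate: linkage disequilibrium between variants,
individual-level genotypes, inbreeding, or realistic sampling error in the
published prevalence estimates (the generated CI bounds are cosmetic, like
the real ones, which the pipeline only ever plots).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import DomainError, ValidationError
from .io_formats import FrequencyTable, PrevalenceRecord, ScoringModel, VariantWeight
from .prs_core import PopulationPRS, all_population_prs

_FREQ_CLIP = 1e-6  # keep simulated frequencies away from exact 0/1


@dataclass(frozen=True)
class SyntheticConfig:
    """Parameters of one synthetic study."""

    n_populations: int = 5
    n_variants: int = 6
    fst: float = 0.005
    ancestral_freq_range: tuple[float, float] = (0.1, 0.9)
    weight_range: tuple[float, float] = (0.07, 0.12)
    eco_slope: float = -50.0  # prevalence units per PRS unit (linear link)
    noise_sd: float = 8.0  # residual prevalence scale, per 100,000
    link: str = "linear"
    baseline: float = 60.0  # intercept on the link scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_populations < 3:
            raise ValidationError("need at least 3 populations")
        if self.n_variants < 1:
            raise ValidationError("need at least 1 variant")
        if not 0.0 < self.fst < 1.0:
            raise DomainError(f"fst must be in (0, 1), got {self.fst}")
        lo, hi = self.ancestral_freq_range
        if not 0.0 < lo <= hi < 1.0:
            raise ValidationError("ancestral_freq_range must sit inside (0, 1)")
        wlo, whi = self.weight_range
        if not 0.0 < wlo <= whi:
            raise ValidationError("weight_range must be positive and ordered")
        if self.noise_sd < 0.0:
            raise ValidationError("noise_sd must be non-negative")
        if self.link not in ("linear", "log"):
            raise ValidationError(f"unknown link {self.link!r}")


@dataclass(frozen=True)
class SyntheticDataset:
    """One generated study with its ground truth attached."""

    model: ScoringModel
    freqs: FrequencyTable
    prevalence: tuple[PrevalenceRecord, ...]
    true_prs: tuple[PopulationPRS, ...]
    config: SyntheticConfig


def _population_codes(k: int) -> list[str]:
    return [f"POP{i:02d}" for i in range(k)]


def simulate_frequencies(
    config: SyntheticConfig, rng: np.random.Generator | None = None
) -> FrequencyTable:
    """Draw a population x variant frequency table under Balding-Nichols drift."""
    rng = np.random.default_rng(config.seed) if rng is None else rng
    F = config.fst
    lo, hi = config.ancestral_freq_range
    p0 = rng.uniform(lo, hi, size=config.n_variants)
    shape = (1.0 - F) / F
    f = rng.beta(p0 * shape, (1.0 - p0) * shape,
                 size=(config.n_populations, config.n_variants))
    f = np.clip(f, _FREQ_CLIP, 1.0 - _FREQ_CLIP)
    variants = tuple(f"rs{900000 + i}" for i in range(config.n_variants))
    return FrequencyTable(
        populations=tuple(_population_codes(config.n_populations)),
        variants=variants,
        freq=f,
        alleles={v: "A" for v in variants},
    )


def simulate_prevalence(
    prs: list[float] | np.ndarray,
    config: SyntheticConfig,
    rng: np.random.Generator | None = None,
) -> list[PrevalenceRecord]:
    """Link prevalence to PRS with slope ``eco_slope`` and noise ``noise_sd``.

    Linear link: prevalence = baseline + eco_slope * PRS + eps, truncated at
    1 per 100,000. Log link: prevalence = exp(baseline + eco_slope * PRS +
    eps). CI bounds are cosmetic (value +/- 1.96 * noise_sd, floored at a
    tenth of the value) to mirror the shape of real records.
    """
    prs = np.asarray(prs, dtype=float)
    if prs.size == 0:
        raise ValidationError("prs vector is empty")
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    eps = rng.normal(0.0, config.noise_sd, size=prs.size)
    eta = config.baseline + config.eco_slope * prs + eps
    if config.link == "linear":
        values = np.maximum(eta, 1.0)
    else:
        values = np.exp(eta)
    half = 1.96 * config.noise_sd
    codes = _population_codes(prs.size)
    records = []
    for code, value in zip(codes, values):
        lo = max(value - half, value * 0.1)
        records.append(
            PrevalenceRecord(
                population=code,
                country=code,
                prevalence=float(value),
                ci_low=float(min(lo, value)),
                ci_high=float(value + half),
                source="synthetic",
            )
        )
    return records


def generate_dataset(config: SyntheticConfig) -> SyntheticDataset:
    """Generate a full synthetic study from one seeded generator.

    Regenerating with an identical config is bit-identical.
    """
    rng = np.random.default_rng(config.seed)
    wlo, whi = config.weight_range
    weights = rng.uniform(wlo, whi, size=config.n_variants)
    freqs = simulate_frequencies(config, rng=rng)
    variants = tuple(
        VariantWeight(rsid=rsid, effect_allele="A", other_allele="C",
                      weight=float(w))
        for rsid, w in zip(freqs.variants, weights)
    )
    model = ScoringModel(variants=variants, score_id="SYNTH", trait="synthetic")
    true_prs = all_population_prs(model, freqs)
    prevalence = simulate_prevalence(
        np.array([s.prs for s in true_prs]), config, rng=rng
    )
    return SyntheticDataset(
        model=model,
        freqs=freqs,
        prevalence=tuple(prevalence),
        true_prs=tuple(true_prs),
        config=config,
    )


# ---------------------------------------------------------------------------
# writers (the exact dialects io_formats reads)
# ---------------------------------------------------------------------------

def write_dataset(dataset: SyntheticDataset, outdir) -> dict[str, str]:
    """Write scoring/frequency/prevalence files for a synthetic study.

    Returns the three file paths keyed by 'scores', 'freqs', 'prev'.
    """
    from pathlib import Path

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    scores = outdir / "synthetic_scores.txt"
    lines = [
        "#pgs_id=SYNTH",
        "#trait_reported=synthetic",
        "rsID\tchr_name\tchr_position\teffect_allele\tother_allele\teffect_weight",
    ]
    for v in dataset.model.variants:
        lines.append(
            f"{v.rsid}\t{v.chrom or ''}\t{v.pos or ''}\t{v.effect_allele}"
            f"\t{v.other_allele or ''}\t{v.weight!r}"
        )
    scores.write_text("\n".join(lines) + "\n", encoding="utf-8")

    freqs = outdir / "synthetic_frequencies.tsv"
    header = ["population"] + [
        f"{rsid}:{dataset.freqs.alleles.get(rsid, 'A')}"
        for rsid in dataset.freqs.variants
    ]
    rows = ["\t".join(header)]
    for i, pop in enumerate(dataset.freqs.populations):
        rows.append(
            "\t".join([pop] + [repr(float(v)) for v in dataset.freqs.freq[i]])
        )
    freqs.write_text("\n".join(rows) + "\n", encoding="utf-8")

    prev = outdir / "synthetic_prevalence.tsv"
    rows = ["population\tcountry\tprevalence\tci_low\tci_high\tsource"]
    for rec in dataset.prevalence:
        rows.append(
            f"{rec.population}\t{rec.country}\t{rec.prevalence!r}"
            f"\t{rec.ci_low!r}\t{rec.ci_high!r}\t{rec.source}"
        )
    prev.write_text("\n".join(rows) + "\n", encoding="utf-8")

    return {"scores": str(scores), "freqs": str(freqs), "prev": str(prev)}
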