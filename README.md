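# ecoprs

Ecological polygenic-risk-score (PRS) analysis: does a population's average
genetic risk burden predict its disease prevalence?

`ecoprs` computes **population-level PRS** from a published scoring file and
population allele frequencies, correlates those scores with published
prevalence estimates, and — because the unit of observation is a population,
so n is tiny — wraps the correlation in a robustness suite: BCa bootstrap,
exact permutation testing, leave-one-out sensitivity, Spearman's rank
correlation, post-hoc power analysis and a per-variant contribution
decomposition. It ships a worked example: the seven-variant Sjögren's
syndrome score **PGS001308** evaluated against 1000 Genomes Phase 3 allele
frequencies for five European populations (CEU, TSI, FIN, GBR, IBS) and
published prevalence estimates for the matching countries.

## The model

Under Hardy–Weinberg diploidy, the expected individual score in a population
is

```
PRS = Σᵢ 2 · βᵢ · fᵢ
```

where βᵢ is the per-copy effect weight of variant *i* and fᵢ the
effect-allele frequency in that population (the factor 2 counts both
chromosome copies). The ecological association is Pearson's r between the
population PRS vector and prevalence, tested with the exact t distribution
(df = n − 2), and cross-examined by resampling. Post-hoc power uses the
Fisher transform C = ½·ln[(1+|r|)/(1−|r|)]:

```
power = Φ(C·√(n−3) − z_{α/2}),    n_required = ⌈(z_{α/2}+z_β)²/C² + 3⌉
```

A Balding–Nichols generator (f ~ Beta(p₀(1−F)/F, (1−p₀)(1−F)/F), variance
F·p₀(1−p₀)) simulates drifted population frequencies with a configurable
prevalence–PRS link, so every stage is testable and calibratable offline.

## Worked example

```bash
ecoprs run \
  --scores src/ecoprs/data/PGS001308.txt \
  --freqs  src/ecoprs/data/frequencies_1kg_phase3_eur.tsv \
  --prev   src/ecoprs/data/prevalence_sjogren_europe.tsv \
  --seed 1 --out report.json
```

or, from Python:

```python
from ecoprs import AnalysisOptions, example_paths, run_full_analysis

report = run_full_analysis(*example_paths(), AnalysisOptions(seed=1))
```

Headline numbers from that report (rounded for display):

| quantity | value |
|---|---|
| PRS: CEU / GBR / FIN / TSI / IBS | 0.370 / 0.368 / 0.350 / 0.349 / 0.317 |
| Pearson r (full-precision PRS, raw prevalence) | −0.407 (p = 0.496, R² = 0.166) |
| Pearson r (PRS rounded to 3 dp) | −0.396 (p = 0.510) |
| Spearman ρ (exact permutation p) | −0.60 (p = 0.350) |
| Exact permutation p (120 pairings, raw scale) | 0.483 |
| BCa bootstrap 95% CI (10,000 iterations, seed 1) | [−1.000, 1.000] |
| Post-hoc power at n = 5 (&#124;r&#124; = 0.396) | 8.6% |
| Populations needed for 80% power | 48 |
| Largest contribution variances | rs2394517 > rs1264319 > rs185819 |

Reading: the highest-scoring populations (CEU, GBR) have *lower* prevalence
than Italy or Spain, so the ecological correlation is negative — but at
n = 5 the bootstrap interval spans essentially [−1, 1] and the permutation
p is ~0.5: the data cannot distinguish the observed trend from noise, and
the power analysis says ~48 populations would be needed to detect an effect
of this size reliably. One of the seven score variants lacks an rsID and is
excluded at harmonization; the report's `harmonization` section records
one `excluded_no_rsid` and six `matched` variants.

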