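# Methods

## Scope and model

`ecoprs` performs an *ecological* association analysis: the observational
unit is a population, not a person. A population's score is the expected
individual PRS under Hardy–Weinberg equilibrium and random mating,

    PRS_k = Σ_i 2 · β_i · f_ik ,

with β_i the per-copy effect weight of variant i and f_ik its effect-allele
frequency in population k. Each term c_ik = 2·β_i·f_ik is variant i's
contribution; the across-population variance of c_i ranks which variants
drive between-population PRS differences. The assumptions worth keeping in
mind: no inbreeding (2pf is exact only at HWE), no linkage-disequilibrium
adjustment between variants, and additivity of per-allele effects. None of
the statistics here licenses individual-level conclusions — a negative
cross-population correlation is compatible with a positive individual-level
effect (the classic ecological fallacy).

## Harmonization

A scoring file and a frequency source rarely agree perfectly on variant
identity and allele orientation. `harmonize` assigns every scoring-model
variant exactly one action:

- `excluded_no_rsid` — a variant without an rsID cannot be matched to an
  rsID-keyed frequency table (the packaged example has one such variant);
- `excluded_missing` — rsID absent from the table;
- `matched` — the table's annotated allele is the effect allele, or the
  table carries no allele annotation and is trusted as-is;
- `strand_flipped` — the table reports the strand complement of the effect
  allele: the frequency is unchanged;
- `allele_swapped` — the table reports the other allele (possibly on the
  opposite strand): the frequency becomes 1 − f;
- `excluded_palindromic` — A/T or C/G variants are strand-ambiguous; the
  default policy keeps them with a warning (the packaged example's variants
  are all retained as printed), `--strict` drops them.

Harmonization is idempotent, the allele swap is an involution, and action
counts always partition the model — all three are property-tested. Output
variant order follows the scoring model, making contribution vectors
deterministic.

## Correlation and its presets

Pearson's r is tested against the exact t distribution with df = n − 2; the
confidence interval uses the Fisher z transform with standard error
1/√(n−3) (omitted, with a flag, for n < 4). Two deliberate presets exist
because at n = 5 third-decimal rounding of the PRS vector visibly moves r:
the `none` preset correlates full-precision scores (r = −0.407, p = 0.496
on the packaged example) and the `3dp` preset rounds the PRS vector to
three decimals first (r = −0.396, p = 0.510); the t statistic always uses
the r actually obtained after any rounding. Every result records which
preset and which prevalence scale (`raw` or natural-`log`) produced it.
Raw prevalence is the default scale. The power section of the pipeline
report quotes the effect size a reader would take from a three-decimal
table, i.e. the `3dp` preset magnitude.

Spearman's ρ is Pearson's r on average ranks; for n ≤ 8 its two-sided p is
computed by exact enumeration of all rank pairings rather than the t
approximation.

## Resampling

**Bootstrap.** Pairs (PRS_k, prevalence_k) are resampled with replacement;
n independent uniform indices per iteration, one seeded generator per call
(a seed is mandatory — there is no silent default). At n = 5 roughly 1–2%
of resamples collapse to fewer than two distinct x or y values, where r is
undefined. The default policy excludes them from the empirical distribution
and reports their count; a `redraw` policy replaces them instead. The
interval is BCa: bias correction z0 = Φ⁻¹(F̂(r_obs)) with ties to the
observed value counted half (at small n exact ties do occur), and the
empirical CDF clamped to (1/(B+1), 1−1/(B+1)) so z0 stays finite;
acceleration a = Σd³ / (6·(Σd²)^{3/2}) from leave-one-out jackknife
deviations d. Adjusted endpoints are clamped to [−1, 1]. When z0 = a = 0
the BCa levels reduce exactly to the percentile levels (unit-tested, and
cross-checked against an independent BCa implementation on non-degenerate
data).

**Permutation.** The null is built by permuting the prevalence vector.
For n! ≤ 40,320 (n ≤ 8) all pairings are enumerated and
p = #{|r_π| ≥ |r_obs|}/n!, identity included, so p is exact with
1/n! ≤ p ≤ 1. Comparisons use an absolute tolerance of 1e−12 so that exact
ties (e.g. the reversal of a symmetric design) count as extreme. Larger n
falls back to Monte-Carlo with the add-one estimator (1+k)/(n_perm+1),
which cannot report p = 0. The exact p is super-uniform under the null —
verified empirically over 2,000 synthetic null datasets.

On the packaged example the exact permutation p is 58/120 ≈ 0.483 on the
raw prevalence scale and 63/120 = 0.525 on the log scale; at n = 5 the two
scales genuinely differ and reports should state which one was used.

## Power

Post-hoc power and required sample size use the Fisher-z approximation
(C = atanh|r|, power = Φ(C√(n−3) − z_{α/2}), n = ⌈(z_{α/2}+z_β)²/C² + 3⌉,
floored at 4). Normal quantiles are computed, never hard-coded. The two
formulas are mutually consistent — power at the required n meets the target
across an |r| grid — and the prediction is validated behaviourally: with
the synthetic generator tuned to a true correlation of 0.396 at K = 48
populations, the permutation test's empirical rejection rate at α = 0.05
lands within a few points of the predicted 80%.

## Synthetic data

The generator emulates the structure, not the biology, of the real inputs.
Frequencies follow the Balding–Nichols drift model, f ~ Beta(p₀(1−F)/F,
(1−p₀)(1−F)/F), with mean p₀ and variance F·p₀(1−p₀); the default
F = 0.005 mimics weak intra-European differentiation, and draws are clipped
1e−6 away from fixation. Ancestral frequencies are uniform on (0.1, 0.9)
and weights uniform on (0.07, 0.12), bracketing the packaged score's
weights so synthetic PRS values land in a comparable band (≈0.3–0.6).
Prevalence is linked to PRS by prevalence = a + b·PRS + ε (linear link,
truncated below at 1 per 100,000) or exp(a + b·PRS + ε); defaults
a = 60, b = −50, σ = 8 produce prevalence values and a correlation strength
of the same order as the worked example. b = 0 yields null datasets for
calibration. The generated CI bounds are cosmetic — mirroring the real
prevalence CIs, which the pipeline never uses in computation.

Not emulated: linkage disequilibrium, individual genotypes, inbreeding,
non-Gaussian prevalence error, publication heterogeneity between prevalence
sources. Passing calibration tests therefore show the *statistics* behave
as designed, not that real epidemiological data meet the generator's
assumptions.

## Numerical conventions and edge cases

- Frequencies and weights are parsed and carried at full precision; any
  rounding is presentational or an explicit preset.
- Constant input vectors raise a loud degenerate-input error, never a
  silent NaN; |r| = 1 is flagged degenerate with p reported as exact 0.
- PRS ranking ties break lexicographically by population code; contribution
  variance ranking ties break by scoring-model order.
- Both variance conventions (÷K and ÷(K−1)) are exposed; the default is the
  sample convention ÷(K−1). The across-population contribution *ranking* is
  the stable, tested contract; variance magnitudes at K = 5 are sensitive
  to the convention.
- End-to-end runs are deterministic given the seed: identical inputs and
  options produce byte-identical JSON reports.

## Problem sizes used in the test suite

Simulation-backed checks run at desk scale, chosen to keep Monte-Carlo
noise well below each assertion's margin: 10 seeds × 10,000 iterations for
the bootstrap checks, 2,000 datasets for null super-uniformity, 500
replicates for slope-sign recovery at K = 40, 200 replicates × 2,000
iterations for small-n CI coverage, and 400 replicates × 1,000 permutations
for the K = 48 power validation.

## Known limitations

- With five populations every interval is wide and the bootstrap
  distribution is dominated by ties and sign flips; results at this n are
  sensitivity analyses, not inference.
- The BCa acceleration and z0 are themselves unstable at n = 5 (the
  jackknife has only five leave-one-out points).
- Harmonization trusts unannotated frequency columns to refer to the effect
  allele; with annotation it can correct strand and allele swaps but cannot
  resolve palindromic variants without external strand information.
- The scoring-file dialect covers the PGS Catalog column set; exotic
  dialects (genome-build lifts, hm_ harmonized columns) are out of scope.
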