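# Methods

## Data model and missingness

Analyses run on either subject-level cohorts (id, sex 1=male/2=female,
age, status 1=control/2=case, one two-character genotype per SNP) or
pre-aggregated 3×3×2 count tables. Genotype strings are normalised
(order- and case-insensitive; `/`/`|` separators tolerated; `00`, `--`,
`NN`, empty → missing). Missing data are handled complete-case **per
analysis**: a subject missing one SNP still contributes to the other
SNP's single-locus tables but is excluded from that pair's two-locus
table. This is why single-locus and two-locus denominators can differ,
and the pipeline logs exclusion counts per analysis. Subjects are
oriented by risk-allele dosage (0/1/2 copies of the declared risk
allele).

## Contingency statistics

Odds ratios are cross-products `(a·d)/(b·c)` with Woolf (log-scale Wald)
95% intervals, `exp(log OR ± 1.96·SE)`, `SE² = 1/a+1/b+1/c+1/d`.
Association p-values are Pearson χ² without continuity correction
(scipy). With a zero cell, the Haldane–Anscombe correction adds 0.5 to
all four cells for the OR and its interval (the p-value still uses the
raw table); a whole zero row/column is a hard error. Breslow-Day
odds-ratio homogeneity uses statsmodels' stratified-table test against
the Mantel-Haenszel common OR (optional Tarone adjustment), with a
direct quadratic solution of the expected-cell equation as a fallback
when the common OR is exactly 1 (where the generic quadratic
degenerates). When two genotype ORs are compared, the two strata are
each genotype-vs-reference 2×2 and deliberately share the reference
cell's counts — the strata are not independent, but this is the
construction that matches how such comparisons are made on profile
tables with a common reference.

The exact Hardy-Weinberg test conditions on the allele counts and sums
the probabilities of all heterozygote counts (same parity) no more
probable than the observed one; the recurrence is anchored at the modal
heterozygote count and normalised at the end, which keeps it stable for
cohort-scale samples (tens of thousands of alleles). A 1-df χ² variant
is available. The gate applied to control genotypes fails at p ≤ 0.01
and is a reportable flag, not a fatal error; it is applied per
population, since pooling populations can produce spurious
heterozygote-deficit failures (Wahlund effect) even when every
population is in equilibrium.

## Logistic regression engine

A frequency-weighted Newton/IRLS maximiser is used for every model fit,
so aggregated count data fit identically to expanded subject records
(this equivalence is asserted in the tests, and the engine is
cross-checked against statsmodels GLM). Convergence: relative
log-likelihood change < 1e-10, at most 100 iterations, zero
initialisation, step-halving to guarantee ascent. Separation is a hard
error (flagged when any |coefficient| exceeds 15 on the log-odds scale —
far beyond any plausible effect in this domain — or when the response is
constant); a singular information matrix raises a rank error naming the
implicated column. No penalisation is applied: the intended inputs have
no empty fitted cells, and silent shrinkage would change the reported
ORs.

Per-term inference is Wald (z = β/SE); nested models are compared by
likelihood-ratio χ² tests.

## RERI and MOVER intervals

`RERI = OR₁₁ − OR₁₀ − OR₀₁ + 1` with all three ORs taken against the
contrast's reference cell. In a disease with prevalence well under a few
percent the OR approximates the RR, so the odds-ratio form approximates
the risk-ratio form of RERI; the synthetic-data oracles expose both OR
and RR matrices, and at baseline risk ≲ 1% they agree within ~2% except
where four risk alleles compound the risk beyond ~3%.

Confidence limits use MOVER — method of variance estimates recovery —
which combines the three asymmetric OR intervals:

    L = RERI − √[(θ₁−l₁)² + (u₂−θ₂)² + (u₃−θ₃)²
                 − 2r₁₂(θ₁−l₁)(u₂−θ₂) − 2r₁₃(θ₁−l₁)(u₃−θ₃)
                 + 2r₂₃(u₂−θ₂)(u₃−θ₃)]

and symmetrically for U with opposite limbs. Because the three 2×2
tables share the reference cell, the log-OR estimators are positively
correlated with covariance `1/c + 1/d` (reference cases/controls);
correlations are taken from this multinomial structure, or equivalently
from the indicator-logistic covariance in the model route. The
correlated form is the default (the independent form, all r = 0, is
available); with shared-reference correlations the closed-form and
model routes produce identical intervals.

The unadjusted count route and the indicator-coded logistic route (three
exposure-cell indicators, reference omitted, restricted to the four
contrast cells) agree to 1e-6 on count-expanded data; the model route
additionally accepts age (years, continuous) and sex (female indicator)
covariates.

## Bootstrap p-values

Resampling is stratified by case/control status — cases and controls are
resampled with replacement separately, preserving both margins, which
respects the retrospective design. On count data this is implemented as
two multinomial draws over the nine cells per replicate and fully
vectorised; the adjusted variant resamples subjects and refits the
model. The two-sided percentile p is `2·min(frac ≤ 0, frac ≥ 0)`,
floored at 1/reps and capped at 1. Replicates with an empty contrast
cell are skipped and counted; more than 10% degenerate replicates flags
the result unstable. Default 10,000 replicates; a seed is mandatory.
Note that the percentile bootstrap of RERI is right-skewed for strong
interactions, so its p-values can be an order of magnitude larger than
a normal approximation to the same interval would suggest — the
calibration simulations in the test suite show the type-I error is
nevertheless close to nominal under additive nulls.

## Genotypic interaction model

Each SNP enters as an additive dosage x ∈ {0,1,2} and a dominance
(heterozygote) indicator z ∈ {0,1,0}. The full model regresses status on
`xA, zA, xB, zB` and the four products `xA·xB, xA·zB, zA·xB, zA·zB`;
per-term ORs are Wald, the global test is a 4-df LRT against the
main-effects model. The reduced model keeps `xA, xB, xA·xB` (additive ×
additive on the multiplicative odds scale). The dominance-reduction test
is an explicit LRT between the two full models with df = the parameter
difference (5 when comparing the 9- and 4-parameter models), reported
alongside the p-value rather than hard-coded, because "removing
dominance" admits more than one reduction.

**Dosage orientation.** By default the additive dosage counts the
*minor* allele of each SNP in the analysed sample — the convention of
the INTERSNP implementation of this model family. The dominance term is
orientation-invariant, and flipping one SNP's coded allele inverts the
A×A and one mixed-term OR while leaving all p-values and the global test
unchanged; with risk alleles that are population-major (as for
rs2200733-T and rs3807989-G) the minor and risk orientations therefore
report reciprocal A×A ORs for the same fit. Risk-allele orientation is
available via `CodingScheme("risk")` and is what the simulation
recovery suite uses, since it maps estimates directly onto generating
parameters. Centred (Cockerham) codings were considered and not needed:
the uncentred minor-allele coding reproduces the reference outputs
exactly.

## Synthetic-data generator

The generator emulates a two-SNP case-control study: two biallelic SNPs
in linkage equilibrium (the motivating loci sit on different
chromosomes), HWE genotype frequencies in the source population, and a
3×3 penetrance matrix in one of three modes — `risk_additive`
(P = b + g_A·e_A + g_B·e_B + g_A·g_B·e_AB; any cell outside (0,1) is a
parameter error, never clipped), `odds_multiplicative`
(logit P = logit(b) + g_A·β_A + g_B·β_B + g_A·g_B·γ), or a custom
matrix. Sampling is retrospective: genotype distributions conditional on
status follow from Bayes' rule, and exactly n_cases/n_controls are
drawn, deterministically per seed. Sex and age are independent of
genotype by default; optional log-odds effects enter the penetrance and
are integrated over an 81-point discretised age grid for the Bayes step,
so subject-level draws follow the stated model exactly within that
discretisation.

Defaults are the conditions of the motivating study: 2,020 cases /
5,315 controls, risk-allele frequencies 0.32 and 0.50 (the control
allele frequencies implied by the bundled tables), baseline risk 0.008
(atrial-fibrillation prevalence in the studied population is ~0.8%),
per-allele odds ratios 1.30 and 1.57, no interaction. Sex/age defaults
(60% male, age ~ N(60, 12²), no disease effect) are typical of AF
case-control cohorts. What the generator does **not** emulate: linkage
disequilibrium, population stratification or admixture, genotyping
error, and age/sex distributions that differ by recruitment site — so
passing recovery tests demonstrate estimator correctness under the
stated model, not robustness to those real-data features.

`TrueValues` carries the exact population quantities (genotype
frequencies, penetrance, OR and RR matrices, true RERI per contrast,
true multiplicative interaction OR) computed by direct arithmetic, and
`recovery_suite` reports bias, CI coverage and rejection rates over
replicates (≥ 50 required for the rates to be meaningful).

## Numerical and design choices

* 95% intervals use z = 1.959963985; ORs/RERIs are printed to 2
  decimals, percentages to 1.
* Reference genotype configurable; default (0,0). An empty reference
  cell raises an error naming usable alternatives.
* Raw p-values are reported; Bonferroni-style thresholds are annotation,
  never an adjustment of the p-values themselves.
* The bundled study tables are analysed at the sizes printed (up to
  7,335 subjects); simulation-based checks in the test suite use 200–500
  replicates at cohort sizes of 2,000–50,000, chosen so each estimator's
  Monte-Carlo error is small relative to the tolerance being asserted.
* The pipeline isolates stage failures (one degenerate SNP pair cannot
  abort the others) and records seed, package version and input SHA-256
  checksums in a JSON manifest; re-running a config with the same seed
  is bit-identical.

## Known limitations

No VCF/BCF parsing, imputation, phasing or multi-allelic support; no
attributable-proportion or synergy-index measures; no genome-wide
pairwise scanning; no correction for population structure (analyses of
stratified samples should be run per population and combined
explicitly, as the pipeline does). The Breslow-Day comparison of two
profile ORs shares the reference cell between strata and should be read
as a descriptive homogeneity check, not a test on independent strata.
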