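# Methods

## Ecological arm

The cross-national analysis treats each country as one observation: an
incidence rate of schizophrenia (per 100,000/year, from a single published
epidemiological study per country) against mean dietary PUFA consumption
(mg/day). Because psychosis onset follows early-life nutrition by decades,
consumption is averaged over a lag window of `lag_years` calendar years
ending the year **before** the study period starts (default 20, i.e. the
window `[period_start − 20, period_start − 1]`); a missing year in the
window is an error, never silently imputed. With `lag_years = 0` the value
at `period_start` is used.

Association is measured by the Pearson product-moment correlation, with a
two-sided p-value from `t = r·sqrt((n−2)/(1−r²))` on `n−2` degrees of
freedom. Socioeconomic confounding is addressed with the first-order
partial correlation controlling for GDP per capita,
`r_xy·z = (r_xy − r_xz·r_yz)/sqrt((1−r_xz²)(1−r_yz²))`, tested on `n−3`
degrees of freedom; the implementation agrees to 1e−10 with the equivalent
residual-on-residual construction (checked against an independent
weighted-regression oracle and against pingouin in the test suite). GDP
enters untransformed by default — a log scale is a defensible alternative
and is exposed as the `log_gdp` config switch, but is not the default
because the qualitative claim (AA remains inversely correlated after
adjustment) holds on the raw scale. No multiple-testing correction is
applied to the primary p-values; the screen output carries a
Benjamini–Hochberg column for transparency.

A caution inherited from the data: the packaged country table stores
consumption to 2 decimal places, so statistics recomputed from it carry
that input rounding. Correlations are stable to ~0.001 under this rounding,
but p-values near a round boundary can cross it (the ω-6 LCPUFA p sits at
0.0011 from the rounded table).

### Diet-exposure stage

Intake is a sum over food commodities: per-capita supply (g/day) is first
reduced by two fractional losses — a wastage index for retail/consumption
loss and a refuse factor for inedible parts — which compose
multiplicatively, `edible = supply·(1−wastage)·(1−refuse)`, because both
are proportional losses of the same physical flow. Edible quantity times
composition content (mg per 100 g) divided by 100 gives mg/day, summed
over commodities. Wastage may be specified per country or per
country-commodity (the finer scope wins); refuse is per commodity.
Commodities without a composition match contribute zero with a logged
warning, since supply-to-composition matching is inherently partial; a
match pointing at a *missing* composition record is an error. Group totals
(total ω-3, total ω-6 and their long-chain subsets) are plain sums over
member species, with long-chain defined as ≥ 20 carbons.

## Mendelian randomization arm

### Instrument handling

Instruments must pass `p < gwas_p_threshold` (default 5×10⁻⁸) and pairwise
LD `r² < ld_r2_threshold` (default 0.1). Pruning is greedy in order of
increasing p: a SNP is kept only if independent of everything already kept,
so the smaller-p member of each dependent pair survives. SNP pairs missing
from the LD table are assumed independent (logged); the multivariable
clumping variant orders SNPs by their best (smallest) association p across
exposures.

Harmonization aligns the outcome effect to the exposure's effect allele:
identical allele → unchanged; swapped alleles → sign flip; incompatible
pairs → error. A/T and C/G (palindromic) SNPs cannot be strand-resolved
from allele codes and are excluded by default with a warning
(`allow_palindromic=True` overrides). Instruments lacking an outcome record
are dropped with a warning; no proxy search is attempted. Standard errors
are never altered by harmonization.

### Estimators

The Wald ratio uses the first-order delta-method SE, `σ_Y/|γ|`, ignoring
exposure-side uncertainty — this is what makes fixed-effect IVW equal to
the precision-weighted mean of Wald ratios, and it is appropriate here
because the instruments are very strong (exposure F ≫ 10). A second-order
SE including the exposure variance term is available behind a flag.
p-values are two-sided from the standard normal, not a t reference.
Exposure effects are on the scale of the source GWAS (percent of total
fatty acids per allele, described there as ~1 SD units); no additional
rescaling is applied since no conversion factor is published.

Multivariable MR solves the weighted normal equations of the outcome
effects on the exposure-effect matrix with weights `1/σ_Y²` and no
intercept; the per-exposure covariance is `(XᵀWX)⁻¹` with no dispersion
scaling (fixed-effect convention). An exposure column that is identically
zero is dropped from the solve and reported as NaN, which makes the
single-exposure reduction exact. Rank-deficient designs raise a
collinearity error naming the exposures.

Conditional instrument strength is a Sanderson–Windmeijer-style statistic:
the target exposure's instrument effects are projected (weighted by their
inverse squared exposure-side SEs) onto the other exposures' effects, and
the mean residual chi-square `(1/L)·Σ eⱼ²/seⱼ²` is reported. When the other
exposures' effects are all zero this reduces exactly to the unconditional
mean chi-square F; exact collinearity gives 0. Covariances between
exposure GWAS estimates are unavailable from separate summary tables and
are ignored, so this is an approximation to the full conditional F.

The univariable instrument-strength statistic follows
`F = (N−k−1)·R²/(1−R²)` with `R² = 2·MAF·(1−MAF)·β²`, which assumes a
variance-standardized exposure; `R² ≥ 1` is rejected as a unit
inconsistency. The packaged instrument tables omit MAF (it is not published
alongside them), so F values for those specific instruments are not
recomputed — the published values all exceed 10 by a wide margin.

### Pleiotropy screens

LD independence between instruments and candidate confounder SNPs treats
cross-chromosome pairs as r² = 0 (physical linkage is impossible) and
reports same-chromosome pairs missing from the LD input as "unknown" rather
than silently independent. The cross-trait screen works from a locally
supplied association table (no web lookups, so results are deterministic
and reproducible offline); traits below genome-wide significance for an
instrument are labelled *vertical* when their class matches a configurable
list of downstream lipid/fatty-acid/metabolite classes, otherwise
*horizontal* for manual review.

## Synthetic data generator

`simulate_two_sample_gwas` emulates the structure of the real inputs:
genotypes are Binomial(2, MAF); a quantitative exposure
`x = Σ effectⱼ·gⱼ + N(0, noise_sd²)` is measured in one cohort; a binary
outcome is sampled in a disjoint cohort from a logistic model with
log-odds `logit(prevalence) + θ·x + pleiotropy·g`. Exposure summary
statistics come from per-SNP least-squares regression and outcome
statistics from per-SNP logistic regression (statsmodels), so outcome
effects are ln odds ratios exactly as in a case-control GWAS. Optional LD
blocks share a latent Gaussian factor per haplotype, thresholded at the
MAF quantile; the latent correlation upper-bounds the realized genotype
r², which is verified empirically in tests rather than guaranteed
analytically.

Defaults mirror the study conditions: 50,000 individuals per arm, three
SNPs with MAFs 0.33/0.25/0.30 and effects 1.69/0.20/0.25 (arachidonic-acid
instrument scale), residual SD 2.5 (AA spans roughly 8–12% of total fatty
acids across cohorts), baseline outcome probability 0.43 (the case
fraction of the outcome GWAS), and causal effect θ = −0.015 = ln(0.986).
The generator does **not** emulate realistic human LD maps, allele-
frequency spectra, population stratification, assortative mating or
selection, so passing recovery tests demonstrates estimator correctness
under the stated model, not robustness to those real-data complications.

`simulate_food_tables` draws random supply, composition, matching and
loss-factor tables and computes the true intake with an independent plain
loop over the defining sum, shipped alongside the tables so the pipeline
can be checked against exact ground truth.

## Numerical choices and test scales

- p-values parsed from text that underflow IEEE doubles (the strongest
  instrument association is printed as 3×10⁻⁹⁷¹) are clamped to the
  smallest positive float rather than 0, preserving the `p > 0` invariant.
- Confidence intervals use the two-sided normal 97.5% point 1.9599639845.
- Readers convert numeric text directly to doubles with no intermediate
  rounding; writers emit `repr` shortest round-trip strings, so
  write-then-read is lossless.
- Simulation-based checks use 20 replicates for parameter recovery
  (asserted within 3 Monte-Carlo standard errors) and 200 replicates for
  null calibration (rejection rate at α = 0.05 asserted within
  [0.02, 0.08]), at 50,000 individuals per arm — large enough that
  weak-instrument bias is negligible, small enough to keep the whole suite
  under a minute.

## Known limitations

- The ecological design cannot rule out residual country-level
  confounding beyond GDP; incidence estimates also differ in diagnostic
  era and coverage (national vs subnational).
- Fixed-effect IVW assumes all instruments estimate one common causal
  effect; with two or three instruments per exposure, heterogeneity and
  pleiotropy-robust estimators (Egger, weighted median) are not
  identifiable and are deliberately out of scope.
- The conditional F ignores cross-exposure estimate covariance (see
  above) and should be read as a screening statistic.
- The "per SD" interpretation of the exposure scale is inherited from the
  source GWAS; no empirical SD conversion is applied.
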