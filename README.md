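# nutrimendel

Tools for studying the relationship between dietary polyunsaturated fatty
acids (PUFAs) and schizophrenia risk with two complementary designs:

1. **Cross-national (ecological) correlation.** Country-level schizophrenia
   incidence rates (per 100,000/year) are correlated with mean dietary PUFA
   consumption (mg/day) averaged over the 20 years preceding each incidence
   study period, with GDP per capita partialled out to control for
   socioeconomic confounding. A diet-exposure stage converts food-supply
   quantities (g/capita/day) into per-PUFA intake using a food-composition
   table, a wastage index for retail/consumption loss and a refuse factor
   for inedible parts.
2. **Two-sample Mendelian randomization (MR).** Genetic variants robustly
   associated with plasma PUFA levels (p < 5×10⁻⁸, pairwise LD r² < 0.1)
   serve as instruments. For each SNP *j* with exposure effect γⱼ (% of
   total fatty acids per allele) and schizophrenia effect Γⱼ (ln OR per
   allele, harmonized to the same effect allele), the Wald ratio is Γⱼ/γⱼ
   and the fixed-effect inverse-variance-weighted (IVW) pooled estimate is

   β̂ = Σⱼ γⱼΓⱼ/σⱼ² ⁄ Σⱼ γⱼ²/σⱼ²,  se(β̂) = (Σⱼ γⱼ²/σⱼ²)^(−1/2),

   with σⱼ the outcome standard error; OR = exp(β̂). Instrument strength is
   F = (N−k−1)·R²/(1−R²) with R² = 2·MAF·(1−MAF)·β². Multivariable MR
   estimates direct effects of two metabolically linked PUFAs jointly by
   weighted least squares of Γ on the exposure-effect matrix, with a
   Sanderson–Windmeijer-style conditional F per exposure. A pleiotropy
   module screens instruments against candidate confounder SNPs (LD
   independence) and a local cross-trait association table.

The package ships the published 24-country analysis table and the
instrument/outcome summary statistics for eight PUFAs (LA, GLA, DGLA, AA,
ALA, EPA, DPA, DHA), plus a synthetic-data module that generates two-sample
GWAS summaries with known causal effects and food-supply tables with known
true intake, so every stage is testable offline.

## Worked example

```python
from nutrimendel import datasets
from nutrimendel.ecological import correlation_screen
from nutrimendel.mr import univariable_mr

countries = datasets.country_table()          # 24 countries
screen = correlation_screen(countries, ["AA", "omega6_lcpufa"])
print(screen[screen.kind == "simple"][["exposure", "r", "p"]])
#         exposure         r         p
# 0             AA -0.576763  0.003174
# 2  omega6_lcpufa -0.625327  0.001085

estimates, forest = univariable_mr(
    datasets.pufa_instruments(), datasets.schizophrenia_outcome()
)
print(estimates[["exposure", "n_snps", "or", "p"]].head(5))
#   exposure  n_snps        or         p
# 0       LA       3  1.008340  0.263489
# 1      GLA       2  0.149005  0.004445
# 2     DGLA       2  0.993761  0.821739
# 3       AA       2  0.985570  0.029995
# 4      ALA       1  3.601138  0.072138
```

Higher arachidonic-acid (AA) consumption correlates with lower
schizophrenia incidence (r = −0.577, p < 0.01; the correlation stays
negative and significant after GDP adjustment), and genetically predicted
AA and GLA are protective in the MR arm (OR 0.986 and 0.149 per unit
exposure), while the ω-3 PUFAs show no significant effect.

The same analyses are available from the shell:

```sh
nutrimendel correlate --out results/corr
nutrimendel mr --out results/mr
nutrimendel simulate --kind gwas --seed 7 --out results/sim
```

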