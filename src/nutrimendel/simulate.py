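"""Synthetic two-sample GWAS and food-table generators with known truth.

The GWAS generator emulates the structure of the real analysis inputs: a
quantitative plasma fatty-acid exposure (percent of total fatty acids)
measured in one cohort, and a case-control outcome sampled under a
logistic model in a second, non-overlapping cohort. Genotypes are
Binomial(2, MAF); optional LD blocks are induced on haplotypes through a
latent Gaussian copula with block-constant correlation (the latent
correlation upper-bounds the realized genotype r^2, which the generator
reports empirically rather than guaranteeing). Exposure summary statistics
come from per-SNP least-squares score regression, outcome statistics from
per-SNP logistic regression, so outcome betas are ln odds ratios exactly
as in a case-control GWAS.

Default parameters mirror the study scale: samples of 50,000 per arm,
three instruments with MAFs 0.33/0.25/0.30 and effects 1.69/0.20/0.25 (%
of total fatty acids per allele, arachidonic-acid-like), residual SD 2.5%,
baseline outcome probability 0.43 (the case fraction of the schizophrenia
GWAS), and a causal log-OR of -0.015 per unit exposure (= ln 0.986).
"""

from __future__ import annotations

from collections.abc import Sequence
from dataclasses import dataclass, field

import numpy as np
import statsmodels.api as sm
from scipy import stats

from .diet import (
    AdjustmentFactors,
    CompositionRecord,
    FoodSupplyRecord,
    IntakeEstimate,
)
from .errors import ValidationError
from .model import SummaryAssociation


@dataclass
class SimulationConfig:
    """Generating parameters for a single-exposure two-sample GWAS."""

    n_exposure_sample: int = 50_000
    n_outcome_sample: int = 50_000
    snp_mafs: tuple[float, ...] = (0.33, 0.25, 0.30)
    snp_effects: tuple[float, ...] = (1.69, 0.20, 0.25)
    causal_effect: float = -0.015
    pleiotropy_effects: tuple[float, ...] | None = None
    baseline_prevalence: float = 0.43
    noise_sd: float = 2.5
    ld_blocks: tuple[tuple[tuple[int, ...], float], ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_exposure_sample, self.n_outcome_sample) < 100:
            raise ValidationError("samples must be >= 100")
        if not (0 < self.baseline_prevalence < 1):
            raise ValidationError("baseline prevalence must lie in (0, 1)")
        if not (self.noise_sd > 0):
            raise ValidationError("noise_sd must be positive")
        if len(self.snp_mafs) != len(self.snp_effects):
            raise ValidationError("snp_mafs and snp_effects must be conformable")
        if any(not (0 < m <= 0.5) for m in self.snp_mafs):
            raise ValidationError("MAFs must lie in (0, 0.5]")
        if self.pleiotropy_effects is not None and len(self.pleiotropy_effects) != len(
            self.snp_mafs
        ):
            raise ValidationError("pleiotropy_effects must be conformable with SNPs")


@dataclass(frozen=True)
class SimulationTruth:
    """Generating parameters frozen alongside the simulated tables."""

    causal_effect: float | tuple[float, ...]
    snp_effects: tuple
    snp_mafs: tuple[float, ...]
    pleiotropy_effects: tuple[float, ...]
    baseline_prevalence: float
    noise_sd: float | tuple[float, ...]
    seed: int


def _genotypes(
    rng: np.random.Generator,
    n: int,
    mafs: Sequence[float],
    ld_blocks: Sequence[tuple[Sequence[int], float]],
) -> np.ndarray:
    """n x m genotype dosages; LD blocks share a latent haplotype factor."""
    m = len(mafs)
    thresholds = stats.norm.ppf(mafs)
    g = np.empty((n, m), dtype=np.int8)
    in_block = set()
    for idx, _ in ld_blocks:
        in_block.update(idx)
    indep = [j for j in range(m) if j not in in_block]
    for hap in range(2):
        z = np.empty((n, m))
        if indep:
            z[:, indep] = rng.standard_normal((n, len(indep)))
        for idx, rho in ld_blocks:
            idx = list(idx)
            shared = rng.standard_normal((n, 1))
            eps = rng.standard_normal((n, len(idx)))
            z[:, idx] = np.sqrt(rho) * shared + np.sqrt(1.0 - rho) * eps
        allele = (z < thresholds).astype(np.int8)
        g = allele if hap == 0 else g + allele
    return g.astype(float)


def _linear_score_stats(g: np.ndarray, x: np.ndarray) -> list[tuple[float, float, float]]:
    """Per-SNP simple-regression (beta, se, p) of exposure on dosage."""
    n = g.shape[0]
    out = []
    xc = x - x.mean()
    for j in range(g.shape[1]):
        gj = g[:, j] - g[:, j].mean()
        sxx = float(gj @ gj)
        beta = float(gj @ xc) / sxx
        resid = xc - beta * gj
        sigma2 = float(resid @ resid) / (n - 2)
        se = np.sqrt(sigma2 / sxx)
        t = beta / se
        out.append((beta, float(se), float(2.0 * stats.t.sf(abs(t), n - 2))))
    return out


def _logistic_score_stats(g: np.ndarray, y: np.ndarray) -> list[tuple[float, float, float]]:
    """Per-SNP logistic-regression (ln OR, se, p) of case status on dosage."""
    out = []
    for j in range(g.shape[1]):
        design = sm.add_constant(g[:, j])
        fit = sm.Logit(y, design).fit(disp=0, maxiter=50)
        beta, se = float(fit.params[1]), float(fit.bse[1])
        z = beta / se
        out.append((beta, se, float(2.0 * stats.norm.sf(abs(z)))))
    return out


def _records(
    per_snp: list[tuple[float, float, float]],
    g: np.ndarray,
    n: int,
) -> list[SummaryAssociation]:
    recs = []
    for j, (beta, se, p) in enumerate(per_snp):
        freq = float(g[:, j].mean() / 2.0)
        maf = min(freq, 1.0 - freq)
        recs.append(
            SummaryAssociation(
                snp_id=f"rs_sim_{j + 1}",
                chromosome=j + 1,
                effect_allele="A",
                other_allele="G",
                beta=beta,
                se=se,
                pval=max(p, 5e-324),
                n=n,
                maf=max(maf, 1e-12),
            )
        )
    return recs


def simulate_two_sample_gwas(
    config: SimulationConfig,
) -> tuple[list[SummaryAssociation], list[SummaryAssociation], SimulationTruth]:
    """Exposure and outcome summary statistics from two disjoint cohorts."""
    rng = np.random.default_rng(config.seed)
    effects = np.asarray(config.snp_effects, dtype=float)
    pleio = (
        np.zeros_like(effects)
        if config.pleiotropy_effects is None
        else np.asarray(config.pleiotropy_effects, dtype=float)
    )

    g_exp = _genotypes(rng, config.n_exposure_sample, config.snp_mafs, config.ld_blocks)
    x = g_exp @ effects + rng.normal(0.0, config.noise_sd, config.n_exposure_sample)
    exposure = _records(
        _linear_score_stats(g_exp, x), g_exp, config.n_exposure_sample
    )

    g_out = _genotypes(rng, config.n_outcome_sample, config.snp_mafs, config.ld_blocks)
    x_out = g_out @ effects + rng.normal(0.0, config.noise_sd, config.n_outcome_sample)
    logit0 = np.log(config.baseline_prevalence / (1.0 - config.baseline_prevalence))
    eta = logit0 + config.causal_effect * x_out + g_out @ pleio
    y = rng.uniform(size=config.n_outcome_sample) < 1.0 / (1.0 + np.exp(-eta))
    outcome = _records(
        _logistic_score_stats(g_out, y.astype(float)), g_out, config.n_outcome_sample
    )

    truth = SimulationTruth(
        causal_effect=config.causal_effect,
        snp_effects=tuple(config.snp_effects),
        snp_mafs=tuple(config.snp_mafs),
        pleiotropy_effects=tuple(pleio.tolist()),
        baseline_prevalence=config.baseline_prevalence,
        noise_sd=config.noise_sd,
        seed=config.seed,
    )
    return exposure, outcome, truth


@dataclass
class MVSimulationConfig:
    """Two-sample generator for several exposures sharing one instrument set."""

    n_exposure_sample: int = 50_000
    n_outcome_sample: int = 50_000
    snp_mafs: tuple[float, ...] = (0.33, 0.25, 0.30)
    #: rows = SNPs, columns = exposures
    snp_effects: tuple[tuple[float, ...], ...] = (
        (1.69, 0.10),
        (0.20, 0.60),
        (0.25, 0.05),
    )
    causal_effects: tuple[float, ...] = (-0.015, 0.0)
    baseline_prevalence: float = 0.43
    noise_sd: tuple[float, ...] = (2.5, 1.0)
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.n_exposure_sample, self.n_outcome_sample) < 100:
            raise ValidationError("samples must be >= 100")
        if len(self.snp_effects) != len(self.snp_mafs):
            raise ValidationError("snp_effects rows must match snp_mafs")
        k = len(self.causal_effects)
        if any(len(row) != k for row in self.snp_effects):
            raise ValidationError("snp_effects columns must match causal_effects")
        if len(self.noise_sd) != k:
            raise ValidationError("noise_sd must have one entry per exposure")


def simulate_mv_two_sample_gwas(
    config: MVSimulationConfig,
) -> tuple[list[list[SummaryAssociation]], list[SummaryAssociation], SimulationTruth]:
    """Per-exposure summary tables plus outcome table for multivariable MR."""
    rng = np.random.default_rng(config.seed)
    B = np.asarray(config.snp_effects, dtype=float)  # m x k
    theta = np.asarray(config.causal_effects, dtype=float)
    sds = np.asarray(config.noise_sd, dtype=float)
    k = theta.size

    g_exp = _genotypes(rng, config.n_exposure_sample, config.snp_mafs, ())
    exposures = []
    for e in range(k):
        x = g_exp @ B[:, e] + rng.normal(0.0, sds[e], config.n_exposure_sample)
        exposures.append(
            _records(_linear_score_stats(g_exp, x), g_exp, config.n_exposure_sample)
        )

    g_out = _genotypes(rng, config.n_outcome_sample, config.snp_mafs, ())
    x_out = g_out @ B + rng.normal(
        0.0, sds, size=(config.n_outcome_sample, k)
    )
    logit0 = np.log(config.baseline_prevalence / (1.0 - config.baseline_prevalence))
    eta = logit0 + x_out @ theta
    y = rng.uniform(size=config.n_outcome_sample) < 1.0 / (1.0 + np.exp(-eta))
    outcome = _records(
        _logistic_score_stats(g_out, y.astype(float)), g_out, config.n_outcome_sample
    )
    truth = SimulationTruth(
        causal_effect=tuple(theta.tolist()),
        snp_effects=tuple(map(tuple, B.tolist())),
        snp_mafs=tuple(config.snp_mafs),
        pleiotropy_effects=tuple([0.0] * len(config.snp_mafs)),
        baseline_prevalence=config.baseline_prevalence,
        noise_sd=tuple(sds.tolist()),
        seed=config.seed,
    )
    return exposures, outcome, truth


@dataclass(frozen=True)
class FoodTables:
    supply: list[FoodSupplyRecord]
    composition: list[CompositionRecord]
    matching: dict[str, str]
    factors: AdjustmentFactors
    truth: list[IntakeEstimate]


def simulate_food_tables(
    n_countries: int,
    n_commodities: int,
    species: Sequence[str],
    seed: int,
    year: int = 2000,
) -> FoodTables:
    """Random supply/composition/matching/factor tables with exact truth intake.

    The truth is computed by an independent plain loop over the same
    definition (adjusted supply times content per 100 g, summed over
    commodities), so pipeline output can be checked against it exactly.
    """
    if n_countries < 1 or n_commodities < 1:
        raise ValidationError("need at least one country and one commodity")
    rng = np.random.default_rng(seed)
    countries = [f"C{i:02d}" for i in range(n_countries)]
    commodities = [f"commodity_{j:02d}" for j in range(n_commodities)]
    items = [f"item_{j:02d}" for j in range(n_commodities)]
    matching = dict(zip(commodities, items))
    supply = [
        FoodSupplyRecord(c, year, cm, float(rng.uniform(0.0, 300.0)))
        for c in countries
        for cm in commodities
    ]
    composition = [
        CompositionRecord(
            it,
            {sp: float(rng.uniform(0.0, 500.0)) for sp in species},
        )
        for it in items
    ]
    factors = AdjustmentFactors(
        wastage={c: float(rng.uniform(0.0, 0.3)) for c in countries},
        refuse={cm: float(rng.uniform(0.0, 0.4)) for cm in commodities},
    )

    # independent truth computation: plain accumulation loop
    comp_lookup = {c.food_item_id: c.pufa_content for c in composition}
    acc: dict[tuple[str, int, str], float] = {}
    for rec in supply:
        item = matching[rec.commodity_id]
        edible = (
            rec.supply
            * (1.0 - factors.wastage[rec.country_code])
            * (1.0 - factors.refuse[rec.commodity_id])
        )
        for sp, mg in comp_lookup[item].items():
            key = (rec.country_code, rec.year, sp)
            acc[key] = acc.get(key, 0.0) + edible * mg / 100.0
    truth = [
        IntakeEstimate(c, y, sp, v) for (c, y, sp), v in sorted(acc.items())
    ]
    return FoodTables(supply, composition, matching, factors, truth)
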