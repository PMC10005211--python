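"""Core domain types shared across the pipeline.

The package works on two kinds of primary records:

* GWAS summary associations — one per SNP-trait pair, carrying the
  per-effect-allele coefficient (a concentration shift in % of total fatty
  acids for a PUFA exposure, a log odds ratio for the case-control outcome),
  its standard error, p-value and sample metadata.
* country-level analysis rows — schizophrenia incidence per 100,000, the
  study period, lagged dietary PUFA consumption in mg/day and GDP per capita.

All types validate their invariants at construction so that downstream
stages can assume well-formed inputs.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from .errors import ValidationError

VALID_ALLELES = frozenset("ACGT")

#: smallest positive double; p-values that underflow parse to this, not 0
TINY_P = 5e-324


@dataclass(frozen=True)
class SummaryAssociation:
    """One SNP-trait association from a GWAS summary-statistics table.

    ``beta`` is per copy of ``effect_allele``: for PUFA exposures it is a
    shift in % of total fatty acids, for the schizophrenia outcome it is
    ln(OR). ``other_allele`` and ``maf`` may be unknown (``None``).
    """

    snp_id: str
    effect_allele: str
    beta: float
    se: float
    pval: float
    chromosome: int | None = None
    nearby_gene: str | None = None
    other_allele: str | None = None
    n: int | None = None
    maf: float | None = None

    def __post_init__(self) -> None:
        if self.effect_allele not in VALID_ALLELES:
            raise ValidationError(
                f"{self.snp_id}: effect allele {self.effect_allele!r} not one of A/C/G/T"
            )
        if self.other_allele is not None:
            if self.other_allele not in VALID_ALLELES:
                raise ValidationError(
                    f"{self.snp_id}: other allele {self.other_allele!r} not one of A/C/G/T"
                )
            if self.other_allele == self.effect_allele:
                raise ValidationError(f"{self.snp_id}: effect and other allele identical")
        if not (self.se > 0) or not math.isfinite(self.se):
            raise ValidationError(f"{self.snp_id}: se must be positive, got {self.se}")
        if not (0 < self.pval <= 1):
            raise ValidationError(f"{self.snp_id}: p-value {self.pval} outside (0, 1]")
        if self.maf is not None and not (0 < self.maf <= 0.5):
            raise ValidationError(f"{self.snp_id}: MAF {self.maf} outside (0, 0.5]")

    @property
    def allele_pair(self) -> frozenset[str] | None:
        if self.other_allele is None:
            return None
        return frozenset((self.effect_allele, self.other_allele))

    def is_palindromic(self) -> bool | None:
        """True for A/T or C/G pairs; None when the other allele is unknown."""
        pair = self.allele_pair
        if pair is None:
            return None
        return pair in (frozenset("AT"), frozenset("CG"))

    def flipped(self) -> "SummaryAssociation":
        """The same association reported on the opposite allele."""
        if self.other_allele is None:
            raise ValidationError(f"{self.snp_id}: cannot flip with unknown other allele")
        return SummaryAssociation(
            snp_id=self.snp_id,
            effect_allele=self.other_allele,
            other_allele=self.effect_allele,
            beta=-self.beta,
            se=self.se,
            pval=self.pval,
            chromosome=self.chromosome,
            nearby_gene=self.nearby_gene,
            n=self.n,
            maf=self.maf,
        )


@dataclass(frozen=True)
class CountryRecord:
    """One row of the cross-national analysis table."""

    country_code: str
    incidence: float
    period_start: int
    period_end: int
    consumption: dict[str, float]
    gdp_per_capita: float
    country_name: str = ""

    def __post_init__(self) -> None:
        if not (self.incidence > 0):
            raise ValidationError(f"{self.country_code}: incidence must be positive")
        if self.period_start > self.period_end:
            raise ValidationError(
                f"{self.country_code}: period {self.period_start}-{self.period_end} reversed"
            )
        for species, value in self.consumption.items():
            if value < 0:
                raise ValidationError(
                    f"{self.country_code}: negative consumption for {species}"
                )


@dataclass(frozen=True)
class PufaSpecies:
    """A polyunsaturated fatty acid, e.g. AA = C20:4 omega-6."""

    name: str
    carbons: int
    double_bonds: int
    family: str  # "omega-3" or "omega-6"

    def __post_init__(self) -> None:
        if self.carbons < 18:
            raise ValidationError(f"{self.name}: PUFA chain length must be >= 18 carbons")
        if self.family not in ("omega-3", "omega-6"):
            raise ValidationError(f"{self.name}: family must be omega-3 or omega-6")

    @property
    def is_long_chain(self) -> bool:
        return self.carbons >= 20


#: dietary and plasma PUFAs handled by name throughout the package
PUFA_REGISTRY: dict[str, PufaSpecies] = {
    s.name: s
    for s in (
        PufaSpecies("LA", 18, 2, "omega-6"),
        PufaSpecies("GLA", 18, 3, "omega-6"),
        PufaSpecies("EDA", 20, 2, "omega-6"),
        PufaSpecies("DGLA", 20, 3, "omega-6"),
        PufaSpecies("AA", 20, 4, "omega-6"),
        PufaSpecies("AdrA", 22, 4, "omega-6"),
        PufaSpecies("ALA", 18, 3, "omega-3"),
        PufaSpecies("SDA", 18, 4, "omega-3"),
        PufaSpecies("ETA", 20, 4, "omega-3"),
        PufaSpecies("EPA", 20, 5, "omega-3"),
        PufaSpecies("DPA", 22, 5, "omega-3"),
        PufaSpecies("DHA", 22, 6, "omega-3"),
    )
}


@dataclass
class AnalysisConfig:
    """Tunable thresholds of the whole pipeline.

    Defaults follow the study design: a 20-year dietary lag before each
    incidence study period, genome-wide instrument significance 5e-8, LD
    independence at r^2 < 0.1 and a 0.05 significance level.
    """

    lag_years: int = 20
    gwas_p_threshold: float = 5e-8
    ld_r2_threshold: float = 0.1
    alpha: float = 0.05
    rng_seed: int = 0
    log_gdp: bool = False  # partial correlation uses raw GDP by default

    def __post_init__(self) -> None:
        if self.lag_years < 0:
            raise ValidationError("lag_years must be >= 0")
        for name in ("gwas_p_threshold", "ld_r2_threshold", "alpha"):
            v = getattr(self, name)
            if not (0 < v < 1):
                raise ValidationError(f"{name} must lie in (0, 1), got {v}")


@dataclass(frozen=True)
class HarmonizedInstrument:
    """Exposure and outcome effects for one SNP on a shared effect allele."""

    snp_id: str
    effect_allele: str
    beta_exposure: float
    se_exposure: float
    beta_outcome: float
    se_outcome: float

    def __post_init__(self) -> None:
        if not (self.se_exposure > 0):
            raise ValidationError(f"{self.snp_id}: se_exposure must be positive")
        if not (self.se_outcome > 0):
            raise ValidationError(f"{self.snp_id}: se_outcome must be positive")


@dataclass(frozen=True)
class MREstimate:
    """Pooled causal estimate on the log-OR scale with per-SNP decomposition."""

    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    z: float
    pval: float
    n_snps: int
    per_snp: tuple = field(default_factory=tuple)  # (snp_id, wald_ratio, wald_se)

    def __post_init__(self) -> None:
        if not (self.ci_low < self.or_ < self.ci_high):
            raise ValidationError("confidence interval does not bracket the OR")
        if not (0 < self.pval <= 1):
            raise ValidationError(f"p-value {self.pval} outside (0, 1]")


@dataclass(frozen=True)
class FStatResult:
    """Instrument-strength summary: R^2 = 2*MAF*(1-MAF)*beta^2 and its F."""

    snp_id: str
    r_squared: float
    f: float
    n: int
    k: int

    @property
    def weak(self) -> bool:
        """Conventional weak-instrument flag (F <= 10)."""
        return self.f <= 10.0
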