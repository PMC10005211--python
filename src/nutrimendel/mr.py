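"""Two-sample univariable Mendelian randomization from summary statistics.

Instruments are SNPs associated with a plasma PUFA at genome-wide
significance (p < 5e-8), pruned to pairwise LD r^2 < 0.1. After aligning
exposure and outcome effects to a shared effect allele, each SNP yields a
Wald ratio Gamma/gamma (outcome ln OR per unit exposure) with first-order
delta-method standard error sigma_Y/|gamma|. The fixed-effect
inverse-variance-weighted (IVW) pooled estimate is

    beta_IVW = sum_j gamma_j Gamma_j / sigma_j^2  /  sum_j gamma_j^2 / sigma_j^2
    se_IVW   = (sum_j gamma_j^2 / sigma_j^2)^(-1/2)

which equals the precision-weighted mean of the Wald ratios and the
weighted-least-squares slope of Gamma on gamma through the origin.
Two-sided p-values use the standard normal. Instrument strength is
summarized by F = (N - k - 1) R^2 / (1 - R^2) with
R^2 = 2 MAF (1 - MAF) beta^2; F > 10 is the conventional adequacy bar.
"""

from __future__ import annotations

import logging
import math
from collections.abc import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import DomainError, HarmonizationError, PalindromicSNPError
from .model import FStatResult, HarmonizedInstrument, MREstimate, SummaryAssociation

log = logging.getLogger(__name__)


def ld_lookup(
    ld: Mapping[tuple[str, str], float] | Iterable,
) -> dict[frozenset, float]:
    """Normalize an LD input (pair->r2 mapping or LDPair iterable) to a symmetric dict."""
    table: dict[frozenset, float] = {}
    if isinstance(ld, Mapping):
        items = [(a, b, r2) for (a, b), r2 in ld.items()]
    else:
        items = [(p.snp_a, p.snp_b, p.r_squared) for p in ld]
    for a, b, r2 in items:
        table[frozenset((a, b))] = float(r2)
    return table


def select_instruments(
    stats_in: Sequence[SummaryAssociation],
    p_threshold: float = 5e-8,
    ld: Mapping | Iterable | None = None,
    r2_threshold: float = 0.1,
) -> list[SummaryAssociation]:
    """Genome-wide-significant SNPs greedily pruned to pairwise r^2 < threshold.

    Candidates are visited in order of increasing p-value; a SNP is kept if
    its r^2 with every already-kept SNP is below the threshold, so the
    smaller-p member of each dependent pair survives. Pairs absent from the
    LD input are assumed independent (logged once).
    """
    table = ld_lookup(ld) if ld is not None else {}
    significant = sorted(
        (s for s in stats_in if s.pval < p_threshold), key=lambda s: s.pval
    )
    kept: list[SummaryAssociation] = []
    warned = False
    for cand in significant:
        dependent = False
        for other in kept:
            key = frozenset((cand.snp_id, other.snp_id))
            if key not in table and not warned:
                log.info("LD pair %s missing; assuming independent", set(key))
                warned = True
            if table.get(key, 0.0) >= r2_threshold:
                dependent = True
                break
        if not dependent:
            kept.append(cand)
    return kept


def harmonize(
    exposure: SummaryAssociation,
    outcome: SummaryAssociation,
    allow_palindromic: bool = False,
) -> HarmonizedInstrument:
    """Express the outcome effect on the exposure's effect allele.

    If the outcome is reported on the exposure's other allele, the outcome
    sign flips; standard errors are unchanged. Incompatible allele pairs
    raise :class:`HarmonizationError`. A/T and C/G SNPs are strand-ambiguous
    from allele codes alone and raise :class:`PalindromicSNPError` unless
    explicitly allowed.
    """
    if exposure.snp_id != outcome.snp_id:
        raise HarmonizationError(
            f"SNP mismatch: {exposure.snp_id} vs {outcome.snp_id}"
        )
    if not allow_palindromic and (
        exposure.is_palindromic() or outcome.is_palindromic()
    ):
        raise PalindromicSNPError(
            f"{exposure.snp_id}: palindromic allele pair, strand unresolved"
        )
    exp_pair, out_pair = exposure.allele_pair, outcome.allele_pair
    if exp_pair is not None and out_pair is not None and exp_pair != out_pair:
        raise HarmonizationError(
            f"{exposure.snp_id}: allele pairs {sorted(exp_pair)} and "
            f"{sorted(out_pair)} are incompatible"
        )
    if outcome.effect_allele == exposure.effect_allele:
        beta_out = outcome.beta
    elif (
        outcome.effect_allele == exposure.other_allele
        or outcome.other_allele == exposure.effect_allele
    ):
        beta_out = -outcome.beta
    else:
        raise HarmonizationError(
            f"{exposure.snp_id}: outcome allele {outcome.effect_allele} matches "
            f"neither exposure allele"
        )
    return HarmonizedInstrument(
        snp_id=exposure.snp_id,
        effect_allele=exposure.effect_allele,
        beta_exposure=exposure.beta,
        se_exposure=exposure.se,
        beta_outcome=beta_out,
        se_outcome=outcome.se,
    )


def harmonize_pairs(
    exposures: Sequence[SummaryAssociation],
    outcomes: Sequence[SummaryAssociation],
    allow_palindromic: bool = False,
) -> list[HarmonizedInstrument]:
    """Harmonize every exposure instrument with its outcome record.

    Instruments with no outcome record, and palindromic SNPs (unless
    allowed), are dropped with a logged warning rather than failing the
    whole analysis.
    """
    by_snp = {o.snp_id: o for o in outcomes}
    result = []
    for exp in exposures:
        out = by_snp.get(exp.snp_id)
        if out is None:
            log.warning("%s: no outcome record; instrument dropped", exp.snp_id)
            continue
        try:
            result.append(harmonize(exp, out, allow_palindromic=allow_palindromic))
        except PalindromicSNPError:
            log.warning("%s: palindromic; instrument dropped", exp.snp_id)
    return result


def wald_ratio(
    inst: HarmonizedInstrument, second_order: bool = False
) -> tuple[float, float]:
    """Per-SNP causal estimate Gamma/gamma and its delta-method SE.

    The default first-order SE, sigma_Y/|gamma|, ignores exposure-side
    uncertainty and matches the fixed-effect IVW weighting. The
    second-order option adds the exposure variance term.
    """
    g = inst.beta_exposure
    if g == 0:
        raise DomainError(f"{inst.snp_id}: exposure beta is zero; ratio undefined")
    ratio = inst.beta_outcome / g
    if second_order:
        se = math.sqrt(
            inst.se_outcome**2 / g**2
            + inst.beta_outcome**2 * inst.se_exposure**2 / g**4
        )
    else:
        se = inst.se_outcome / abs(g)
    return ratio, se


def ivw_fixed(instruments: Sequence[HarmonizedInstrument]) -> MREstimate:
    """Fixed-effect inverse-variance-weighted pooled causal estimate."""
    if not instruments:
        raise DomainError("IVW requires at least one instrument")
    for inst in instruments:
        if inst.beta_exposure == 0:
            raise DomainError(f"{inst.snp_id}: exposure beta is zero")
    g = np.array([i.beta_exposure for i in instruments])
    G = np.array([i.beta_outcome for i in instruments])
    s = np.array([i.se_outcome for i in instruments])
    w = g**2 / s**2
    beta = float(np.sum(g * G / s**2) / np.sum(w))
    se = float(np.sum(w) ** -0.5)
    z = beta / se
    pval = float(2.0 * stats.norm.sf(abs(z)))
    half = 1.959963984540054 * se
    per_snp = tuple(
        (inst.snp_id, *wald_ratio(inst)) for inst in instruments
    )
    return MREstimate(
        beta=beta,
        se=se,
        or_=math.exp(beta),
        ci_low=math.exp(beta - half),
        ci_high=math.exp(beta + half),
        z=z,
        pval=max(pval, 5e-324),
        n_snps=len(instruments),
        per_snp=per_snp,
    )


def f_statistic(assoc: SummaryAssociation, k: int) -> FStatResult:
    """Instrument strength from MAF and effect size.

    R^2 = 2 MAF (1-MAF) beta^2 is the variance in the (standardized)
    exposure explained by the SNP; F = (N - k - 1) R^2 / (1 - R^2) with N
    the GWAS sample size and k the number of instruments.
    """
    if assoc.maf is None:
        raise DomainError(f"{assoc.snp_id}: MAF unknown; F statistic unavailable")
    if assoc.n is None or assoc.n <= k + 1:
        raise DomainError(f"{assoc.snp_id}: need sample size n > k + 1")
    r2 = 2.0 * assoc.maf * (1.0 - assoc.maf) * assoc.beta**2
    if r2 >= 1.0:
        raise DomainError(
            f"{assoc.snp_id}: R^2 = {r2:.3f} >= 1; beta units inconsistent with "
            "a standardized exposure"
        )
    f = (assoc.n - k - 1) * r2 / (1.0 - r2)
    return FStatResult(snp_id=assoc.snp_id, r_squared=r2, f=f, n=assoc.n, k=k)


def univariable_mr(
    exposures: Mapping[str, Sequence[SummaryAssociation]],
    outcome: Sequence[SummaryAssociation],
    allow_palindromic: bool = False,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """IVW MR for every exposure against one outcome table.

    Returns (estimates, forest): one row per exposure with the pooled OR,
    CI and p-value, and the per-SNP forest-plot table across exposures.
    """
    est_rows, forest_frames = [], []
    for name, exp_records in exposures.items():
        instruments = harmonize_pairs(
            exp_records, outcome, allow_palindromic=allow_palindromic
        )
        if not instruments:
            log.warning("%s: no usable instruments; skipped", name)
            continue
        estimate = ivw_fixed(instruments)
        est_rows.append(
            {
                "exposure": name,
                "n_snps": estimate.n_snps,
                "beta": estimate.beta,
                "se": estimate.se,
                "or": estimate.or_,
                "ci_low": estimate.ci_low,
                "ci_high": estimate.ci_high,
                "p": estimate.pval,
            }
        )
        forest_frames.append(mr_report(name, instruments, estimate))
    estimates = pd.DataFrame(est_rows)
    forest = (
        pd.concat(forest_frames, ignore_index=True)
        if forest_frames
        else pd.DataFrame(columns=["exposure", "snp", "or", "ci_low", "ci_high"])
    )
    return estimates, forest


def mr_report(
    exposure_name: str,
    instruments: Sequence[HarmonizedInstrument],
    estimate: MREstimate,
) -> pd.DataFrame:
    """Forest-plot data: one OR + 95% CI row per SNP plus the pooled IVW row."""
    rows = []
    for snp_id, ratio, se in estimate.per_snp:
        half = 1.959963984540054 * se
        rows.append(
            {
                "exposure": exposure_name,
                "snp": snp_id,
                "or": math.exp(ratio),
                "ci_low": math.exp(ratio - half),
                "ci_high": math.exp(ratio + half),
            }
        )
    rows.append(
        {
            "exposure": exposure_name,
            "snp": "IVW (pooled)",
            "or": estimate.or_,
            "ci_low": estimate.ci_low,
            "ci_high": estimate.ci_high,
        }
    )
    return pd.DataFrame(rows)
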