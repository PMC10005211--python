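"""Multivariable two-sample Mendelian randomization.

Direct effects of K exposures are estimated jointly by weighted least
squares of the outcome associations Gamma_j on the K-column matrix of
exposure associations gamma_jk, with no intercept and weights
1/sigma_Yj^2:

    theta_hat = (X' W X)^{-1} X' W Gamma,   cov = (X' W X)^{-1}

Per-exposure conditional instrument strength follows the
Sanderson-Windmeijer idea: regress the target exposure's instrument betas
on the other exposures' betas (weighted by the target's exposure-side
variances) and summarize the residual signal as a mean chi-square,

    F_cond = (1/L) sum_j e_j^2 / se_jk^2 .

With all other-exposure betas zero this reduces exactly to the
unconditional mean-chi-square instrument F, and perfectly collinear
exposure betas give F_cond = 0. Covariances between exposure estimates are
ignored (they are unavailable from separate summary tables), so this is an
approximation to the full conditional F.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .errors import CollinearityError, DomainError, ValidationError
from .mr import ld_lookup

_Z95 = 1.959963984540054


@dataclass(frozen=True)
class MVInstrument:
    """One SNP's associations with every exposure and the outcome, shared allele."""

    snp_id: str
    effect_allele: str
    beta_exposures: tuple[float, ...]
    se_exposures: tuple[float, ...]
    beta_outcome: float
    se_outcome: float

    def __post_init__(self) -> None:
        if len(self.beta_exposures) < 2:
            raise ValidationError(f"{self.snp_id}: need >= 2 exposures")
        if len(self.beta_exposures) != len(self.se_exposures):
            raise ValidationError(f"{self.snp_id}: beta/se length mismatch")
        if any(se <= 0 for se in self.se_exposures) or self.se_outcome <= 0:
            raise ValidationError(f"{self.snp_id}: standard errors must be positive")

    def min_p(self) -> float:
        """Smallest per-exposure association p-value (normal approximation)."""
        z = [abs(b) / s for b, s in zip(self.beta_exposures, self.se_exposures)]
        return float(2.0 * stats.norm.sf(max(z)))


@dataclass(frozen=True)
class ExposureEstimate:
    beta: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    pval: float


@dataclass(frozen=True)
class MVMREstimate:
    exposures: tuple[str, ...]
    estimates: tuple[ExposureEstimate, ...]
    n_snps: int
    conditional_f: tuple[float, ...] = field(default_factory=tuple)


def clump(
    instruments: Sequence[MVInstrument],
    ld: Mapping | Iterable | None,
    r2_threshold: float = 0.1,
) -> list[MVInstrument]:
    """Greedy LD pruning keeping the strongest (smallest min-p) SNP per block."""
    table = ld_lookup(ld) if ld is not None else {}
    ordered = sorted(instruments, key=lambda i: i.min_p())
    kept: list[MVInstrument] = []
    for cand in ordered:
        if all(
            table.get(frozenset((cand.snp_id, other.snp_id)), 0.0) < r2_threshold
            for other in kept
        ):
            kept.append(cand)
    # preserve input ordering for the survivors
    surviving = {i.snp_id for i in kept}
    return [i for i in instruments if i.snp_id in surviving]


def _design(
    instruments: Sequence[MVInstrument],
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    X = np.array([i.beta_exposures for i in instruments], dtype=float)
    y = np.array([i.beta_outcome for i in instruments], dtype=float)
    w = np.array([1.0 / i.se_outcome**2 for i in instruments], dtype=float)
    return X, y, w


def mvmr_ivw(
    instruments: Sequence[MVInstrument],
    exposure_names: Sequence[str] | None = None,
) -> MVMREstimate:
    """Joint direct effects of all exposures by weighted least squares."""
    if not instruments:
        raise DomainError("no instruments supplied")
    X, y, w = _design(instruments)
    n_snps, k = X.shape
    names = tuple(exposure_names or [f"exposure_{i+1}" for i in range(k)])
    if len(names) != k:
        raise ValidationError("exposure_names length does not match design")
    if n_snps < k:
        raise DomainError(
            f"need at least as many instruments ({n_snps}) as exposures ({k})"
        )
    nonzero = [i for i in range(k) if np.any(X[:, i] != 0)]
    Xr = X[:, nonzero]
    if np.linalg.matrix_rank(Xr) < Xr.shape[1]:
        raise CollinearityError(
            f"exposure beta matrix is rank deficient across {names}"
        )
    # all-zero columns are estimable only as 0; solve on the reduced design
    beta = np.zeros(k)
    cov = np.full((k, k), np.nan)
    xtx_r = (Xr * w[:, None]).T @ Xr
    beta_r = np.linalg.solve(xtx_r, (Xr * w[:, None]).T @ y)
    cov_r = np.linalg.inv(xtx_r)
    for out_i, i in enumerate(nonzero):
        beta[i] = beta_r[out_i]
        for out_j, j in enumerate(nonzero):
            cov[i, j] = cov_r[out_i, out_j]
    estimates = []
    for i in range(k):
        if i in nonzero:
            se = math.sqrt(cov[i, i])
            z = beta[i] / se
            pval = float(2.0 * stats.norm.sf(abs(z)))
            half = _Z95 * se
            estimates.append(
                ExposureEstimate(
                    beta=float(beta[i]),
                    se=se,
                    or_=math.exp(beta[i]),
                    ci_low=math.exp(beta[i] - half),
                    ci_high=math.exp(beta[i] + half),
                    pval=max(pval, 5e-324),
                )
            )
        else:
            estimates.append(
                ExposureEstimate(math.nan, math.nan, math.nan, math.nan, math.nan, math.nan)
            )
    cond_f = tuple(
        conditional_f(instruments, i)
        if i in nonzero and k >= 2 and n_snps > k
        else math.nan
        for i in range(k)
    )
    return MVMREstimate(
        exposures=names,
        estimates=tuple(estimates),
        n_snps=n_snps,
        conditional_f=cond_f,
    )


def conditional_f(instruments: Sequence[MVInstrument], exposure_index: int) -> float:
    """Conditional instrument strength of one exposure given the others.

    Weighted projection of the target exposure's betas onto the other
    exposures' betas (weights = inverse squared exposure-side SEs of the
    target), then the mean residual chi-square. Equals the unconditional
    mean chi-square when the other exposures' betas are all zero; equals 0
    when the target betas are an exact linear combination of the others.
    """
    X, _, _ = _design(instruments)
    n_snps, k = X.shape
    if k < 2:
        raise DomainError("conditional F needs >= 2 exposures")
    if not (0 <= exposure_index < k):
        raise DomainError(f"exposure index {exposure_index} out of range")
    if n_snps <= k:
        raise DomainError("need more instruments than exposures")
    target = X[:, exposure_index]
    others = np.delete(X, exposure_index, axis=1)
    se_t = np.array([i.se_exposures[exposure_index] for i in instruments])
    w = 1.0 / se_t**2
    if np.any(others != 0):
        sw = np.sqrt(w)
        coef, *_ = np.linalg.lstsq(others * sw[:, None], target * sw, rcond=None)
        resid = target - others @ coef
    else:
        resid = target
    return float(np.mean(resid**2 * w))
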