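"""Cross-national correlation of dietary PUFA consumption with incidence.

For each exposure the screen reports a simple Pearson product-moment
correlation of the country incidence rates against lagged mean consumption,
and a first-order partial correlation adjusting for GDP per capita:

    r_xy.z = (r_xy - r_xz * r_yz) / sqrt((1 - r_xz^2) (1 - r_yz^2))

Two-sided p-values come from t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of
freedom (n-3 for the partial). GDP enters untransformed by default; a
log-transform switch is provided since the correct scale is a modelling
choice. No multiple-testing correction is applied to the primary p-values,
but a Benjamini-Hochberg column is included in the screen output for
transparency.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Sequence
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import DomainError, ValidationError
from .model import CountryRecord


@dataclass(frozen=True)
class CorrelationResult:
    r: float
    n: int
    t_stat: float
    pval: float
    kind: str  # "simple" or "partial"
    adjusted_for: str | None = None

    def __post_init__(self) -> None:
        if not (-1.0 <= self.r <= 1.0):
            raise ValidationError(f"correlation {self.r} outside [-1, 1]")


def _as_array(v: Sequence[float], name: str) -> np.ndarray:
    arr = np.asarray(v, dtype=float)
    if arr.ndim != 1:
        raise DomainError(f"{name} must be one-dimensional")
    if np.ptp(arr) == 0:
        raise DomainError(f"{name} is constant; correlation undefined")
    return arr


def pearson(x: Sequence[float], y: Sequence[float]) -> CorrelationResult:
    """Simple Pearson product-moment correlation with a two-sided t test."""
    xa, ya = _as_array(x, "x"), _as_array(y, "y")
    if xa.size != ya.size:
        raise DomainError("x and y must have equal length")
    n = xa.size
    if n < 3:
        raise DomainError("need at least 3 observations")
    r = float(stats.pearsonr(xa, ya).statistic)
    return CorrelationResult(r=r, n=n, **_t_test(r, n, df=n - 2), kind="simple")


def _t_test(r: float, n: int, df: int) -> dict:
    if abs(r) == 1.0:
        return {"t_stat": math.inf if r > 0 else -math.inf, "pval": 0.0}
    t = r * math.sqrt(df / (1.0 - r * r))
    return {"t_stat": t, "pval": float(2.0 * stats.t.sf(abs(t), df))}


def partial_pearson(
    x: Sequence[float],
    y: Sequence[float],
    z: Sequence[float],
    adjusted_for: str = "z",
) -> CorrelationResult:
    """First-order partial correlation of x and y controlling for z."""
    xa, ya, za = _as_array(x, "x"), _as_array(y, "y"), _as_array(z, "z")
    if not (xa.size == ya.size == za.size):
        raise DomainError("x, y, z must have equal length")
    n = xa.size
    if n < 4:
        raise DomainError("need at least 4 observations for a first-order partial")
    r_xy = float(stats.pearsonr(xa, ya).statistic)
    r_xz = float(stats.pearsonr(xa, za).statistic)
    r_yz = float(stats.pearsonr(ya, za).statistic)
    if abs(r_xz) == 1.0 or abs(r_yz) == 1.0:
        raise DomainError("covariate is perfectly collinear with x or y")
    r = (r_xy - r_xz * r_yz) / math.sqrt((1 - r_xz**2) * (1 - r_yz**2))
    r = min(1.0, max(-1.0, r))
    return CorrelationResult(
        r=r, n=n, **_t_test(r, n, df=n - 3), kind="partial", adjusted_for=adjusted_for
    )


def correlation_screen(
    records: Iterable[CountryRecord],
    exposures: Sequence[str],
    log_gdp: bool = False,
) -> pd.DataFrame:
    """Simple and GDP-adjusted correlations for each exposure.

    Returns a tidy frame with one simple and one partial row per exposure
    (columns: exposure, kind, r, n, t, p, p_bh). Rows with a missing
    exposure value in any country raise a validation error naming the
    countries involved.
    """
    records = list(records)
    out_rows = []
    if not exposures:
        return pd.DataFrame(columns=["exposure", "kind", "r", "n", "t", "p", "p_bh"])
    incidence = [rec.incidence for rec in records]
    gdp = [rec.gdp_per_capita for rec in records]
    if log_gdp:
        gdp = [math.log(g) for g in gdp]
    for exposure in exposures:
        missing = [r.country_code for r in records if exposure not in r.consumption]
        if missing:
            raise ValidationError(
                f"exposure {exposure!r} absent for countries {missing}"
            )
        values = [rec.consumption[exposure] for rec in records]
        simple = pearson(incidence, values)
        partial = partial_pearson(incidence, values, gdp, adjusted_for="gdp_per_capita")
        for res in (simple, partial):
            out_rows.append(
                {
                    "exposure": exposure,
                    "kind": res.kind,
                    "r": res.r,
                    "n": res.n,
                    "t": res.t_stat,
                    "p": res.pval,
                }
            )
    df = pd.DataFrame(out_rows)
    df["p_bh"] = np.nan
    for kind in ("simple", "partial"):
        mask = df["kind"] == kind
        if mask.any():
            df.loc[mask, "p_bh"] = multipletests(df.loc[mask, "p"], method="fdr_bh")[1]
    return df


def scatter_data(
    records: Iterable[CountryRecord], exposure: str
) -> pd.DataFrame:
    """Per-country (x = consumption, y = incidence) pairs for plotting."""
    rows = [
        {
            "country": r.country_code,
            "x": r.consumption[exposure],
            "y": r.incidence,
        }
        for r in records
    ]
    return pd.DataFrame(rows)
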