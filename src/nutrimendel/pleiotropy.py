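"""Confounder screening for the MR instruments.

Two checks replace manual lookups:

* ``ld_screen`` — pairwise LD independence between each instrument and each
  candidate confounder SNP (e.g. genome-wide-significant CRP loci). Pairs
  on different chromosomes cannot be physically linked and count as r^2 = 0;
  same-chromosome pairs missing from the supplied LD table are reported as
  "unknown", never silently independent.
* ``crosstrait_screen`` — a local cross-trait association table screened at
  genome-wide significance, labelling each flagged trait as vertical
  pleiotropy (a downstream lipid/PUFA metabolic trait, benign for MR) or
  horizontal (a potential bias source needing manual review).
"""

from __future__ import annotations

from collections.abc import Iterable, Mapping, Sequence
from dataclasses import dataclass

import pandas as pd

from .errors import ValidationError

#: trait classes treated as downstream of plasma PUFA levels
DEFAULT_VERTICAL_CLASSES = (
    "lipid",
    "fatty acid",
    "pufa",
    "cholesterol",
    "triglyceride",
    "metabolite",
)


@dataclass(frozen=True)
class LDPair:
    """Symmetric pairwise LD between two SNPs."""

    snp_a: str
    snp_b: str
    r_squared: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.r_squared <= 1.0):
            raise ValidationError(
                f"r^2 {self.r_squared} for ({self.snp_a}, {self.snp_b}) outside [0, 1]"
            )

    @property
    def key(self) -> frozenset:
        return frozenset((self.snp_a, self.snp_b))


def ld_screen(
    instruments: Mapping[str, int],
    candidates: Mapping[str, int],
    ld: Iterable[LDPair],
    threshold: float = 0.1,
) -> pd.DataFrame:
    """One row per instrument x candidate pair with an independence verdict.

    ``instruments`` and ``candidates`` map SNP id to chromosome. Status is
    "independent" (r^2 < threshold, or different chromosomes), "dependent",
    or "unknown" (same chromosome, no LD entry supplied).
    """
    table = {p.key: p.r_squared for p in ld}
    rows = []
    for inst, inst_chr in instruments.items():
        for cand, cand_chr in candidates.items():
            if inst_chr != cand_chr:
                r2, status = 0.0, "independent"
            else:
                key = frozenset((inst, cand))
                if key in table:
                    r2 = table[key]
                    status = "independent" if r2 < threshold else "dependent"
                else:
                    r2, status = float("nan"), "unknown"
            rows.append(
                {"instrument": inst, "candidate": cand, "r2": r2, "status": status}
            )
    return pd.DataFrame(rows)


def ld_screen_verdict(screen: pd.DataFrame) -> str:
    """"no LD confounding" only when every pair is affirmatively independent."""
    if screen.empty or (screen["status"] == "independent").all():
        return "no LD confounding"
    if (screen["status"] == "dependent").any():
        return "LD confounding detected"
    return "inconclusive (unknown pairs)"


def crosstrait_screen(
    instrument_snps: Sequence[str],
    associations: pd.DataFrame,
    gw_threshold: float = 5e-8,
    vertical_classes: Sequence[str] = DEFAULT_VERTICAL_CLASSES,
) -> pd.DataFrame:
    """Traits associated with any instrument below the significance threshold.

    ``associations`` needs columns ``snp``, ``trait``, ``pval`` and may carry
    ``trait_class``; classification matches the trait class (or, absent that,
    the trait name) case-insensitively against ``vertical_classes``. Traits
    not matching any vertical class are labelled "horizontal" for manual
    review.
    """
    required = {"snp", "trait", "pval"}
    missing = required - set(associations.columns)
    if missing:
        raise ValidationError(f"association table missing columns {sorted(missing)}")
    snps = set(instrument_snps)
    hits = associations[
        associations["snp"].isin(snps) & (associations["pval"] < gw_threshold)
    ].copy()
    classes = [c.lower() for c in vertical_classes]

    def label(row) -> str:
        text = str(row.get("trait_class") or row["trait"]).lower()
        return (
            "vertical"
            if any(cls in text or text in cls for cls in classes)
            else "horizontal"
        )

    hits["pleiotropy"] = hits.apply(label, axis=1) if len(hits) else []
    return hits.reset_index(drop=True)
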