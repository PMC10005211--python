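"""Readers and writers for the delimited-text interchange formats.

Two table dialects are understood:

* summary-statistics tables: ``snp, chr, gene, effect_allele, other_allele,
  beta, se, pval, n, maf`` (``other_allele``, ``maf`` and the annotation
  columns optional); tab- or comma-delimited, detected automatically.
* country tables: ``code, country, period, incidence_per_100k,
  <one column per PUFA exposure in mg/day>, gdp_per_capita``.

Parsing is lossless: numeric text is converted straight to IEEE doubles with
no intermediate rounding, and alleles are upper-cased but otherwise stored
as given (harmonization owns all allele logic). Printed p-values smaller
than the double-precision underflow limit (e.g. 3.00e-971) are clamped to
the smallest positive float so the ``pval > 0`` invariant holds.
"""

from __future__ import annotations

import csv
import logging
import math
import re
from collections.abc import Iterable, Mapping
from pathlib import Path

import yaml

from .errors import ConfigurationError, ParseError, ValidationError
from .model import TINY_P, AnalysisConfig, CountryRecord, SummaryAssociation

log = logging.getLogger(__name__)

SUMMARY_COLUMNS = (
    "snp", "chr", "gene", "effect_allele", "other_allele",
    "beta", "se", "pval", "n", "maf",
)
_MANDATORY_SUMMARY = ("snp", "effect_allele", "beta", "se", "pval")

_COUNTRY_FIXED = ("code", "country", "period", "incidence_per_100k", "gdp_per_capita")

_PERIOD_RE = re.compile(r"^\s*(\d{4})\s*(?:[-–—/]\s*(\d{4}))?\s*$")


def _sniff_rows(path: str | Path) -> list[list[str]]:
    text = Path(path).read_text()
    sample = text[:4096]
    try:
        dialect = csv.Sniffer().sniff(sample, delimiters=",\t;")
        delim = dialect.delimiter
    except csv.Error:
        delim = "\t" if "\t" in sample else ","
    return [row for row in csv.reader(text.splitlines(), delimiter=delim) if row]


def _parse_float(raw: str, what: str, rownum: int) -> float:
    try:
        value = float(raw)
    except ValueError:
        raise ParseError(f"non-numeric {what} {raw!r}", row=rownum) from None
    return value


def read_summary_associations(
    path: str | Path, dialect: Mapping[str, str] | None = None
) -> list[SummaryAssociation]:
    """Read a GWAS summary-statistics table into SummaryAssociation records.

    ``dialect`` maps canonical column names (``snp``, ``beta``, ...) to the
    names actually used in the file's header. Rows with missing or
    non-numeric beta/se raise :class:`ParseError` naming the row — they are
    never silently dropped. Missing mandatory columns raise
    :class:`ConfigurationError` naming the column.
    """
    rows = _sniff_rows(path)
    if not rows:
        raise ConfigurationError(f"{path}: empty file, no header row")
    header = [h.strip() for h in rows[0]]
    mapping = dict(dialect or {})
    colidx: dict[str, int] = {}
    for canonical in SUMMARY_COLUMNS:
        actual = mapping.get(canonical, canonical)
        if actual in header:
            colidx[canonical] = header.index(actual)
    for canonical in _MANDATORY_SUMMARY:
        if canonical not in colidx:
            raise ConfigurationError(
                f"{path}: mandatory column {mapping.get(canonical, canonical)!r} "
                f"({canonical}) missing from header {header}"
            )

    def cell(row: list[str], canonical: str) -> str:
        idx = colidx.get(canonical)
        if idx is None or idx >= len(row):
            return ""
        return row[idx].strip()

    records: list[SummaryAssociation] = []
    for rownum, row in enumerate(rows[1:], start=2):
        snp = cell(row, "snp")
        beta_raw, se_raw = cell(row, "beta"), cell(row, "se")
        for what, raw in (("beta", beta_raw), ("se", se_raw)):
            if raw in ("", "NA", "NaN", "nan", "."):
                raise ParseError(f"missing {what} for {snp or '<unnamed SNP>'}", row=rownum)
        beta = _parse_float(beta_raw, "beta", rownum)
        se = _parse_float(se_raw, "se", rownum)
        pval_raw = cell(row, "pval")
        pval = _parse_float(pval_raw, "pval", rownum) if pval_raw else 1.0
        if pval == 0.0 and pval_raw not in ("0", "0.0"):
            pval = TINY_P  # printed value underflowed double precision
        other = cell(row, "other_allele").upper() or None
        chrom_raw, n_raw, maf_raw = cell(row, "chr"), cell(row, "n"), cell(row, "maf")
        try:
            records.append(
                SummaryAssociation(
                    snp_id=snp,
                    chromosome=int(chrom_raw) if chrom_raw else None,
                    nearby_gene=cell(row, "gene") or None,
                    effect_allele=cell(row, "effect_allele").upper(),
                    other_allele=other,
                    beta=beta,
                    se=se,
                    pval=pval,
                    n=int(float(n_raw)) if n_raw else None,
                    maf=_parse_float(maf_raw, "maf", rownum) if maf_raw else None,
                )
            )
        except ValidationError as exc:
            raise ParseError(str(exc), row=rownum) from exc
    return records


def write_summary_associations(
    path: str | Path, records: Iterable[SummaryAssociation], sep: str = "\t"
) -> None:
    """Write records in the canonical summary-statistics layout."""
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(SUMMARY_COLUMNS)
        for r in records:
            writer.writerow(
                [
                    r.snp_id,
                    "" if r.chromosome is None else r.chromosome,
                    r.nearby_gene or "",
                    r.effect_allele,
                    r.other_allele or "",
                    repr(r.beta),
                    repr(r.se),
                    repr(r.pval),
                    "" if r.n is None else r.n,
                    "" if r.maf is None else repr(r.maf),
                ]
            )


def parse_period(raw: str) -> tuple[int, int]:
    """Parse "1965-1994" (hyphen or en dash) or a single year "1967"."""
    m = _PERIOD_RE.match(raw)
    if not m:
        raise ParseError(f"unparseable study period {raw!r}")
    start = int(m.group(1))
    end = int(m.group(2)) if m.group(2) else start
    return start, end


def read_country_table(path: str | Path) -> list[CountryRecord]:
    """Read the country-level analysis table.

    Every header column outside the fixed set (code, country, period,
    incidence_per_100k, gdp_per_capita) is treated as a PUFA exposure in
    mg/day and collected into the record's consumption map.
    """
    rows = _sniff_rows(path)
    if not rows:
        raise ConfigurationError(f"{path}: empty file, no header row")
    header = [h.strip() for h in rows[0]]
    for col in ("code", "period", "incidence_per_100k", "gdp_per_capita"):
        if col not in header:
            raise ConfigurationError(f"{path}: mandatory column {col!r} missing")
    pufa_cols = [c for c in header if c not in _COUNTRY_FIXED]
    records: list[CountryRecord] = []
    seen: set[str] = set()
    for rownum, row in enumerate(rows[1:], start=2):
        get = lambda col: row[header.index(col)].strip()
        code = get("code")
        if code in seen:
            raise ValidationError(f"{path}: duplicate country code {code!r}")
        seen.add(code)
        start, end = parse_period(get("period"))
        consumption = {
            col: _parse_float(get(col), col, rownum) for col in pufa_cols
        }
        records.append(
            CountryRecord(
                country_code=code,
                country_name=get("country") if "country" in header else "",
                incidence=_parse_float(get("incidence_per_100k"), "incidence", rownum),
                period_start=start,
                period_end=end,
                consumption=consumption,
                gdp_per_capita=_parse_float(get("gdp_per_capita"), "gdp", rownum),
            )
        )
    return records


def write_country_table(
    path: str | Path, records: Iterable[CountryRecord], sep: str = ","
) -> None:
    records = list(records)
    pufa_cols: list[str] = []
    for r in records:
        for k in r.consumption:
            if k not in pufa_cols:
                pufa_cols.append(k)
    with open(path, "w", newline="") as fh:
        writer = csv.writer(fh, delimiter=sep)
        writer.writerow(["code", "country", "period", "incidence_per_100k", *pufa_cols,
                         "gdp_per_capita"])
        for r in records:
            period = (
                str(r.period_start)
                if r.period_start == r.period_end
                else f"{r.period_start}-{r.period_end}"
            )
            writer.writerow(
                [
                    r.country_code,
                    r.country_name,
                    period,
                    repr(r.incidence),
                    *[repr(r.consumption.get(c, math.nan)) for c in pufa_cols],
                    repr(r.gdp_per_capita),
                ]
            )


def load_config(path: str | Path) -> AnalysisConfig:
    """Load an AnalysisConfig from a YAML key-value file."""
    raw = yaml.safe_load(Path(path).read_text()) or {}
    if not isinstance(raw, dict):
        raise ConfigurationError(f"{path}: expected a mapping of config keys")
    known = set(AnalysisConfig.__dataclass_fields__)
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"{path}: unknown config keys {sorted(unknown)}")
    return AnalysisConfig(**raw)
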