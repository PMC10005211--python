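"""Packaged reference tables.

``country_table()`` is the 24-country analysis table (incidence per 100,000,
lagged mean dietary AA/DHA/omega-6-LC/omega-3-LC consumption in mg/day and
GDP per capita averaged over the 20 years before each study period).
``pufa_instruments()`` and ``schizophrenia_outcome()`` are the published
genetic instruments for eight plasma PUFAs (CHARGE consortium GWAS scale,
% of total fatty acids per allele) and their schizophrenia associations
(PGC case-control GWAS, ln OR per allele).

The outcome table reports each SNP on a single reference allele, so
harmonization must flip signs where an exposure is reported on the opposite
allele (e.g. rs174547 for AA). MAF is not available for these instruments.

``crp_instrument_ld()`` is a synthetic stand-in for the LD lookup between
the four genome-wide-significant CRP SNPs and the two PUFA instruments on
chromosomes 11 and 16: the published analysis reports only that all pairs
have r^2 < 0.1, so the shipped r^2 values are synthetic placeholders
consistent with that independence, not measured values.
"""

from __future__ import annotations

import csv
from importlib import resources

from .io import read_country_table, read_summary_associations
from .model import CountryRecord, SummaryAssociation
from .pleiotropy import LDPair

#: exposures with printed country-level consumption columns
COUNTRY_EXPOSURES = ("AA", "DHA", "omega6_lcpufa", "omega3_lcpufa")


def _data_path(name: str):
    return resources.files("nutrimendel.data").joinpath(name)


def country_table() -> list[CountryRecord]:
    """The 24-country incidence/consumption/GDP analysis table."""
    with resources.as_file(_data_path("country_pufa_incidence.csv")) as p:
        return read_country_table(p)


def pufa_instruments() -> dict[str, list[SummaryAssociation]]:
    """Genetic instruments grouped per PUFA (8 exposures, 16 instrument rows)."""
    with resources.as_file(_data_path("pufa_instruments.tsv")) as p:
        records = read_summary_associations(p)  # extra 'pufa' column is ignored
        with open(p, newline="") as fh:
            labels = [row["pufa"] for row in csv.DictReader(fh, delimiter="\t")]
    by_pufa: dict[str, list[SummaryAssociation]] = {}
    for label, rec in zip(labels, records, strict=True):
        by_pufa.setdefault(label, []).append(rec)
    return by_pufa


def schizophrenia_outcome() -> list[SummaryAssociation]:
    """Schizophrenia ln-OR associations for every instrument SNP."""
    with resources.as_file(_data_path("scz_outcome.tsv")) as p:
        return read_summary_associations(p)


def crp_instrument_ld() -> list[LDPair]:
    """Synthetic LD r^2 between CRP loci and the PUFA instruments (see module docstring)."""
    with resources.as_file(_data_path("crp_instrument_ld_synthetic.csv")) as p:
        with open(p, newline="") as fh:
            return [
                LDPair(row["snp_a"], row["snp_b"], float(row["r2"]))
                for row in csv.DictReader(fh)
            ]
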