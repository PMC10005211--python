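"""Food-supply to PUFA-intake conversion.

Per-capita commodity supply (g/day, food-balance-sheet style) is adjusted
for retail/consumption wastage and inedible refuse, matched to food items
in a composition database (mg PUFA per 100 g edible portion), and summed
into per-country, per-year, per-species intake in mg/day. Group totals
(total omega-3/omega-6, and their long-chain subsets at >= 20 carbons) are
direct sums over member species. The ecological arm consumes the mean
intake over a lag window ending the year before each incidence study
period.

Wastage and refuse are fractional losses of the same physical flow, so
they compose multiplicatively: edible consumed = supply x (1-wastage) x
(1-refuse). Wastage may be given per country or, more finely, per
country-commodity; the finer scope wins when both are present.
"""

from __future__ import annotations

import logging
from collections.abc import Iterable, Mapping
from dataclasses import dataclass, field

from .errors import DomainError, ValidationError
from .model import PUFA_REGISTRY, PufaSpecies

log = logging.getLogger(__name__)

GROUPS = ("total omega-3", "total omega-6", "total omega-3 LCPUFA", "total omega-6 LCPUFA")


@dataclass(frozen=True)
class FoodSupplyRecord:
    country_code: str
    year: int
    commodity_id: str
    supply: float  # g/capita/day

    def __post_init__(self) -> None:
        if self.supply < 0:
            raise ValidationError(
                f"{self.country_code}/{self.commodity_id}: negative supply"
            )


@dataclass(frozen=True)
class CompositionRecord:
    """PUFA content of one food item, mg per 100 g edible portion."""

    food_item_id: str
    pufa_content: Mapping[str, float]  # species name -> mg/100 g

    def __post_init__(self) -> None:
        for species, mg in self.pufa_content.items():
            if mg < 0:
                raise ValidationError(f"{self.food_item_id}: negative {species} content")


@dataclass(frozen=True)
class AdjustmentFactors:
    """Fractional losses: wastage by country or (country, commodity), refuse by commodity."""

    wastage: Mapping[str, float] = field(default_factory=dict)
    wastage_by_commodity: Mapping[tuple[str, str], float] = field(default_factory=dict)
    refuse: Mapping[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, table in (
            ("wastage", self.wastage),
            ("wastage_by_commodity", self.wastage_by_commodity),
            ("refuse", self.refuse),
        ):
            for key, frac in table.items():
                if not (0 <= frac < 1):
                    raise DomainError(f"{name}[{key!r}] = {frac} outside [0, 1)")

    def resolve(self, country: str, commodity: str) -> tuple[float, float]:
        """(wastage, refuse) for a flow; country-commodity wastage wins over country."""
        wastage = self.wastage_by_commodity.get(
            (country, commodity), self.wastage.get(country, 0.0)
        )
        return wastage, self.refuse.get(commodity, 0.0)


@dataclass(frozen=True)
class IntakeEstimate:
    country_code: str
    year: int
    species: str
    intake: float  # mg/day

    def __post_init__(self) -> None:
        if self.intake < 0:
            raise ValidationError(
                f"{self.country_code}/{self.species}: negative intake"
            )


def read_supply_csv(path) -> list[FoodSupplyRecord]:
    """Supply CSV: country, year, commodity, g_per_capita_day."""
    import csv

    with open(path, newline="") as fh:
        return [
            FoodSupplyRecord(
                row["country"], int(row["year"]), row["commodity"],
                float(row["g_per_capita_day"]),
            )
            for row in csv.DictReader(fh)
        ]


def read_composition_csv(path) -> list[CompositionRecord]:
    """Composition CSV (long form): food_item, species, mg_per_100g."""
    import csv

    content: dict[str, dict[str, float]] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            content.setdefault(row["food_item"], {})[row["species"]] = float(
                row["mg_per_100g"]
            )
    return [CompositionRecord(item, pufas) for item, pufas in content.items()]


def read_matching_csv(path) -> dict[str, str]:
    """Matching CSV: commodity, food_item."""
    import csv

    with open(path, newline="") as fh:
        return {row["commodity"]: row["food_item"] for row in csv.DictReader(fh)}


def read_factors_csv(path) -> AdjustmentFactors:
    """Factors CSV: scope (country | commodity | country_commodity), key, wastage, refuse.

    Country rows set the per-country wastage, commodity rows the per-commodity
    refuse, and country_commodity rows (key "COUNTRY:COMMODITY") the
    commodity-specific wastage override.
    """
    import csv

    wastage: dict[str, float] = {}
    wastage_cc: dict[tuple[str, str], float] = {}
    refuse: dict[str, float] = {}
    with open(path, newline="") as fh:
        for row in csv.DictReader(fh):
            scope, key = row["scope"], row["key"]
            if scope == "country":
                wastage[key] = float(row["wastage"])
            elif scope == "commodity":
                refuse[key] = float(row["refuse"])
            elif scope == "country_commodity":
                country, _, commodity = key.partition(":")
                wastage_cc[(country, commodity)] = float(row["wastage"])
            else:
                raise ValidationError(f"unknown factors scope {scope!r}")
    return AdjustmentFactors(
        wastage=wastage, wastage_by_commodity=wastage_cc, refuse=refuse
    )


def adjust_supply(supply: float, wastage: float, refuse: float) -> float:
    """Edible consumed quantity after retail/consumption loss and refuse removal."""
    if supply < 0:
        raise DomainError(f"supply must be >= 0, got {supply}")
    if not (0 <= wastage < 1):
        raise DomainError(f"wastage {wastage} outside [0, 1)")
    if not (0 <= refuse < 1):
        raise DomainError(f"refuse {refuse} outside [0, 1)")
    return supply * (1.0 - wastage) * (1.0 - refuse)


def estimate_intake(
    supply: Iterable[FoodSupplyRecord],
    matching: Mapping[str, str],
    composition: Iterable[CompositionRecord],
    factors: AdjustmentFactors | None = None,
) -> list[IntakeEstimate]:
    """Aggregate commodity supplies into per-country-year-species intake (mg/day).

    ``matching`` maps supply commodity ids to composition food items.
    Commodities absent from ``matching`` contribute nothing (a warning is
    logged once per commodity); a matched food item missing from
    ``composition`` is an error.
    """
    factors = factors or AdjustmentFactors()
    comp_by_item = {c.food_item_id: c for c in composition}
    for commodity, item in matching.items():
        if item not in comp_by_item:
            raise ValidationError(
                f"matching points commodity {commodity!r} at missing food item {item!r}"
            )
    totals: dict[tuple[str, int, str], float] = {}
    warned: set[str] = set()
    for rec in supply:
        item = matching.get(rec.commodity_id)
        if item is None:
            if rec.commodity_id not in warned:
                log.warning(
                    "commodity %r has no composition match; contributes 0",
                    rec.commodity_id,
                )
                warned.add(rec.commodity_id)
            continue
        wastage, refuse = factors.resolve(rec.country_code, rec.commodity_id)
        edible = adjust_supply(rec.supply, wastage, refuse)
        for species, mg_per_100g in comp_by_item[item].pufa_content.items():
            key = (rec.country_code, rec.year, species)
            totals[key] = totals.get(key, 0.0) + edible * mg_per_100g / 100.0
    return [
        IntakeEstimate(country_code=c, year=y, species=s, intake=v)
        for (c, y, s), v in sorted(totals.items())
    ]


def aggregate_groups(
    estimates: Iterable[IntakeEstimate],
    registry: Mapping[str, PufaSpecies] | None = None,
) -> dict[str, float]:
    """Sum species intakes into the four family/chain-length group totals.

    Long-chain membership is carbons >= 20. Species missing from the
    registry raise a validation error (family unknown).
    """
    registry = registry or PUFA_REGISTRY
    out = {g: 0.0 for g in GROUPS}
    for est in estimates:
        species = registry.get(est.species)
        if species is None:
            raise ValidationError(f"unknown PUFA species {est.species!r}")
        family = "total " + species.family
        out[family] += est.intake
        if species.is_long_chain:
            out[family + " LCPUFA"] += est.intake
    return out


def lag_average(
    series: Mapping[int, float], period_start: int, lag_years: int
) -> float:
    """Mean intake over the ``lag_years`` calendar years before ``period_start``.

    The window is [period_start - lag_years, period_start - 1]; with
    ``lag_years = 0`` the value at ``period_start`` itself is returned.
    Any year missing from the series is an error (no silent imputation).
    """
    if lag_years < 0:
        raise DomainError("lag_years must be >= 0")
    if lag_years == 0:
        if period_start not in series:
            raise ValidationError(f"year {period_start} missing from series")
        return series[period_start]
    window = range(period_start - lag_years, period_start)
    missing = [y for y in window if y not in series]
    if missing:
        raise ValidationError(f"lag window years missing from series: {missing}")
    return sum(series[y] for y in window) / lag_years
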