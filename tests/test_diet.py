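"""Supply-to-intake conversion, group aggregation and the lagged mean."""

import pytest
from hypothesis import given
from hypothesis import strategies as st

from nutrimendel.diet import (
    AdjustmentFactors,
    CompositionRecord,
    FoodSupplyRecord,
    IntakeEstimate,
    adjust_supply,
    aggregate_groups,
    estimate_intake,
    lag_average,
)
from nutrimendel.errors import DomainError, ValidationError
from nutrimendel.simulate import simulate_food_tables


class TestAdjustSupply:
    def test_losses_compose_multiplicatively(self):
        assert adjust_supply(100.0, 0.10, 0.20) == pytest.approx(72.0)

    @given(st.floats(0, 1e4, allow_nan=False))
    def test_no_losses_is_identity(self, s):
        assert adjust_supply(s, 0.0, 0.0) == s

    def test_zero_supply(self):
        assert adjust_supply(0.0, 0.5, 0.5) == 0.0

    @given(
        st.floats(0, 1e4),
        st.floats(0, 0.999),
        st.floats(0, 0.999),
    )
    def test_never_exceeds_supply_never_negative(self, s, w, r):
        adjusted = adjust_supply(s, w, r)
        assert 0.0 <= adjusted <= s

    @pytest.mark.parametrize("wastage,refuse", [(-0.1, 0.0), (1.0, 0.0), (0.0, 1.5)])
    def test_factor_domain_errors(self, wastage, refuse):
        with pytest.raises(DomainError):
            adjust_supply(10.0, wastage, refuse)


class TestEstimateIntake:
    def test_single_commodity(self):
        est = estimate_intake(
            [FoodSupplyRecord("AAA", 2000, "fish", 100.0)],
            {"fish": "fish_item"},
            [CompositionRecord("fish_item", {"AA": 250.0})],
        )
        assert est == [IntakeEstimate("AAA", 2000, "AA", 250.0)]

    def test_two_commodities_sum(self):
        est = estimate_intake(
            [
                FoodSupplyRecord("AAA", 2000, "fish", 100.0),
                FoodSupplyRecord("AAA", 2000, "oil", 50.0),
            ],
            {"fish": "i1", "oil": "i2"},
            [
                CompositionRecord("i1", {"DHA": 100.0}),
                CompositionRecord("i2", {"DHA": 100.0}),
            ],
        )
        assert est[0].intake == pytest.approx(150.0)

    def test_empty_supply(self):
        assert estimate_intake([], {}, []) == []

    def test_unmatched_commodity_contributes_zero(self, caplog):
        est = estimate_intake(
            [
                FoodSupplyRecord("AAA", 2000, "fish", 100.0),
                FoodSupplyRecord("AAA", 2000, "mystery", 500.0),
            ],
            {"fish": "i1"},
            [CompositionRecord("i1", {"AA": 100.0})],
        )
        assert est[0].intake == pytest.approx(100.0)
        assert any("mystery" in r.message for r in caplog.records)

    def test_matching_to_missing_item_rejected(self):
        with pytest.raises(ValidationError, match="ghost"):
            estimate_intake(
                [FoodSupplyRecord("AAA", 2000, "fish", 1.0)],
                {"fish": "ghost"},
                [CompositionRecord("i1", {"AA": 1.0})],
            )

    def test_country_commodity_wastage_overrides_country(self):
        factors = AdjustmentFactors(
            wastage={"AAA": 0.5},
            wastage_by_commodity={("AAA", "fish"): 0.1},
        )
        est = estimate_intake(
            [FoodSupplyRecord("AAA", 2000, "fish", 100.0)],
            {"fish": "i1"},
            [CompositionRecord("i1", {"AA": 100.0})],
            factors,
        )
        assert est[0].intake == pytest.approx(90.0)

    @given(st.floats(1.0, 3.0))
    def test_scale_equivariance(self, c):
        supply = [
            FoodSupplyRecord("AAA", 2000, "fish", 80.0),
            FoodSupplyRecord("AAA", 2000, "oil", 20.0),
        ]
        comp = [
            CompositionRecord("i1", {"AA": 120.0, "DHA": 30.0}),
            CompositionRecord("i2", {"AA": 5.0}),
        ]
        matching = {"fish": "i1", "oil": "i2"}
        base = estimate_intake(supply, matching, comp)
        scaled = estimate_intake(
            [
                FoodSupplyRecord(s.country_code, s.year, s.commodity_id, s.supply * c)
                for s in supply
            ],
            matching,
            comp,
        )
        for b, s in zip(base, scaled):
            assert s.intake == pytest.approx(c * b.intake)

    def test_monotone_in_supply(self):
        comp = [CompositionRecord("i1", {"AA": 120.0, "DHA": 30.0})]
        lo = estimate_intake(
            [FoodSupplyRecord("AAA", 2000, "fish", 50.0)], {"fish": "i1"}, comp
        )
        hi = estimate_intake(
            [FoodSupplyRecord("AAA", 2000, "fish", 60.0)], {"fish": "i1"}, comp
        )
        assert all(h.intake >= l.intake for l, h in zip(lo, hi))


class TestAggregateGroups:
    def test_family_and_chain_membership(self):
        groups = aggregate_groups(
            [
                IntakeEstimate("AAA", 2000, "LA", 100.0),
                IntakeEstimate("AAA", 2000, "AA", 10.0),
            ]
        )
        assert groups["total omega-6"] == pytest.approx(110.0)
        assert groups["total omega-6 LCPUFA"] == pytest.approx(10.0)

    def test_c18_omega3_not_long_chain(self):
        groups = aggregate_groups([IntakeEstimate("AAA", 2000, "ALA", 50.0)])
        assert groups["total omega-3"] == pytest.approx(50.0)
        assert groups["total omega-3 LCPUFA"] == 0.0

    def test_empty_input_all_zero(self):
        assert set(aggregate_groups([]).values()) == {0.0}

    def test_unknown_species_rejected(self):
        with pytest.raises(ValidationError, match="margarine"):
            aggregate_groups([IntakeEstimate("AAA", 2000, "margarine", 1.0)])

    def test_conservation_group_totals_equal_species_sums(self):
        estimates = [
            IntakeEstimate("AAA", 2000, sp, v)
            for sp, v in [("LA", 10.0), ("GLA", 1.0), ("AA", 3.0), ("AdrA", 0.5),
                          ("ALA", 7.0), ("EPA", 2.0), ("DPA", 0.3), ("DHA", 4.0)]
        ]
        groups = aggregate_groups(estimates)
        assert groups["total omega-6"] == pytest.approx(14.5)
        assert groups["total omega-6 LCPUFA"] == pytest.approx(3.5)
        assert groups["total omega-3"] == pytest.approx(13.3)
        assert groups["total omega-3 LCPUFA"] == pytest.approx(6.3)


class TestLagAverage:
    def test_constant_series(self):
        series = {y: 5.0 for y in range(1980, 2000)}
        assert lag_average(series, 2000, 20) == pytest.approx(5.0)

    def test_two_year_window(self):
        assert lag_average({1998: 10.0, 1999: 20.0}, 2000, 2) == pytest.approx(15.0)

    def test_zero_lag_returns_period_start_value(self):
        assert lag_average({2000: 7.0}, 2000, 0) == 7.0

    def test_missing_years_listed(self):
        with pytest.raises(ValidationError, match="1998"):
            lag_average({1999: 20.0}, 2000, 2)


def test_pipeline_recovers_synthetic_truth():
    """End-to-end intake matches the generator's independent truth loop."""
    tables = simulate_food_tables(n_countries=3, n_commodities=5,
                                  species=["AA", "DHA", "LA", "ALA"], seed=7)
    est = estimate_intake(
        tables.supply, tables.matching, tables.composition, tables.factors
    )
    assert len(est) == len(tables.truth)
    for got, want in zip(est, tables.truth):
        assert (got.country_code, got.year, got.species) == (
            want.country_code, want.year, want.species
        )
        assert got.intake == pytest.approx(want.intake, abs=1e-9)
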