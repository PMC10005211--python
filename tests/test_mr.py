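"""Instrument selection, harmonization, Wald ratios and fixed-effect IVW."""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from nutrimendel.errors import DomainError, HarmonizationError, PalindromicSNPError
from nutrimendel.model import HarmonizedInstrument, SummaryAssociation
from nutrimendel.mr import (
    f_statistic,
    harmonize,
    harmonize_pairs,
    ivw_fixed,
    mr_report,
    select_instruments,
    univariable_mr,
    wald_ratio,
)


def assoc(snp="rs1", ea="A", oa="G", beta=0.1, se=0.01, pval=1e-9, **kw):
    return SummaryAssociation(snp_id=snp, effect_allele=ea, other_allele=oa,
                              beta=beta, se=se, pval=pval, **kw)


class TestSelectInstruments:
    def test_p_threshold_filter(self):
        stats = [assoc(snp=f"rs{i}", pval=p) for i, p in
                 enumerate([1e-10, 1e-9, 1e-6])]
        kept = select_instruments(stats, p_threshold=5e-8, ld={})
        assert sorted(s.snp_id for s in kept) == ["rs0", "rs1"]

    @pytest.mark.parametrize("order", [(0, 1), (1, 0)])
    def test_dependent_pair_keeps_smaller_p(self, order):
        a = assoc(snp="rsA", pval=1e-12)
        b = assoc(snp="rsB", pval=1e-9)
        stats = [[a, b][i] for i in order]
        kept = select_instruments(stats, ld={("rsA", "rsB"): 0.5})
        assert [s.snp_id for s in kept] == ["rsA"]

    def test_empty_input(self):
        assert select_instruments([], ld={}) == []


class TestHarmonize:
    def test_matching_alleles_unchanged(self):
        exp = assoc(snp="rs174547", ea="T", oa="C", beta=1.691, se=0.025)
        out = assoc(snp="rs174547", ea="T", oa="C", beta=-0.0205, se=0.0114,
                    pval=0.072)
        h = harmonize(exp, out)
        assert h.beta_outcome == -0.0205
        assert h.effect_allele == "T"

    def test_swapped_alleles_flip_sign(self):
        exp = assoc(snp="rs174547", ea="T", oa="C", beta=1.691, se=0.025)
        out = assoc(snp="rs174547", ea="C", oa="T", beta=0.0205, se=0.0114,
                    pval=0.072)
        h = harmonize(exp, out)
        assert h.beta_outcome == pytest.approx(-0.0205)
        assert h.se_outcome == 0.0114  # SEs never change

    def test_incompatible_allele_pairs_rejected(self):
        exp = assoc(ea="T", oa="C")
        out = assoc(ea="A", oa="G", beta=-0.02, se=0.01, pval=0.5)
        with pytest.raises(HarmonizationError):
            harmonize(exp, out)

    def test_palindromic_excluded_by_default(self):
        exp = assoc(ea="A", oa="T")
        out = assoc(ea="A", oa="T", beta=0.02, se=0.01, pval=0.5)
        with pytest.raises(PalindromicSNPError):
            harmonize(exp, out)
        h = harmonize(exp, out, allow_palindromic=True)
        assert h.beta_outcome == 0.02

    def test_pairs_drops_instruments_without_outcome(self, caplog):
        exp = [assoc(snp="rs1"), assoc(snp="rs_missing")]
        out = [assoc(snp="rs1", beta=0.02, se=0.01, pval=0.5)]
        got = harmonize_pairs(exp, out)
        assert [h.snp_id for h in got] == ["rs1"]
        assert any("rs_missing" in r.message for r in caplog.records)


class TestWaldRatio:
    def test_single_ala_instrument(self):
        inst = HarmonizedInstrument("rs174547", "C", 0.016, 0.001, 0.0205, 0.0114)
        ratio, se = wald_ratio(inst)
        assert math.exp(ratio) == pytest.approx(3.601, abs=0.001)

    def test_null_outcome_gives_zero_ratio(self):
        inst = HarmonizedInstrument("rs1", "A", 0.5, 0.01, 0.0, 0.01)
        assert wald_ratio(inst)[0] == 0.0

    def test_direct_arithmetic(self):
        inst = HarmonizedInstrument("rs1", "A", 2.0, 0.1, 1.0, 0.2)
        ratio, se = wald_ratio(inst)
        assert (ratio, se) == (0.5, pytest.approx(0.1))

    def test_zero_exposure_beta_rejected(self):
        with pytest.raises(DomainError):
            wald_ratio(HarmonizedInstrument("rs1", "A", 0.0, 0.1, 1.0, 0.2))

    def test_second_order_se_is_larger(self):
        inst = HarmonizedInstrument("rs1", "A", 0.5, 0.2, 0.3, 0.1)
        assert wald_ratio(inst, second_order=True)[1] > wald_ratio(inst)[1]


def harmonized(exposures, outcome):
    return harmonize_pairs(exposures, outcome)


class TestIVW:
    def test_aa_pooled_or(self, instruments_by_pufa, scz_outcome):
        est = ivw_fixed(harmonized(instruments_by_pufa["AA"], scz_outcome))
        assert est.or_ == pytest.approx(0.986, abs=0.001)
        assert est.pval == pytest.approx(0.030, abs=0.002)

    def test_gla_pooled_or(self, instruments_by_pufa, scz_outcome):
        est = ivw_fixed(harmonized(instruments_by_pufa["GLA"], scz_outcome))
        assert 0.148 <= round(est.or_, 3) <= 0.149
        assert est.pval == pytest.approx(0.004, abs=0.002)

    def test_la_pooled_or(self, instruments_by_pufa, scz_outcome):
        est = ivw_fixed(harmonized(instruments_by_pufa["LA"], scz_outcome))
        assert est.or_ == pytest.approx(1.008, abs=0.001)

    def test_single_instrument_equals_wald(self, instruments_by_pufa, scz_outcome):
        inst = harmonized(instruments_by_pufa["ALA"], scz_outcome)
        est = ivw_fixed(inst)
        ratio, se = wald_ratio(inst[0])
        assert est.beta == pytest.approx(ratio, abs=0)
        assert est.se == pytest.approx(se, abs=0)

    def test_empty_rejected(self):
        with pytest.raises(DomainError):
            ivw_fixed([])

    def test_weighted_least_squares_oracle(self, instruments_by_pufa, scz_outcome):
        """IVW equals the WLS-through-origin slope of Gamma on gamma, weights 1/sigma^2."""
        import statsmodels.api as sm

        for pufa, exp in instruments_by_pufa.items():
            inst = harmonized(exp, scz_outcome)
            g = np.array([i.beta_exposure for i in inst])
            G = np.array([i.beta_outcome for i in inst])
            w = 1.0 / np.array([i.se_outcome for i in inst]) ** 2
            fit = sm.WLS(G, g, weights=w).fit()
            est = ivw_fixed(inst)
            assert est.beta == pytest.approx(float(fit.params[0]), abs=1e-10)

    def test_pooled_se_never_exceeds_any_wald_se(self, instruments_by_pufa,
                                                 scz_outcome):
        for exp in instruments_by_pufa.values():
            inst = harmonized(exp, scz_outcome)
            est = ivw_fixed(inst)
            assert est.se <= min(se for _, _, se in est.per_snp) + 1e-15

    def test_allele_flip_invariance(self, instruments_by_pufa, scz_outcome):
        """Re-reporting any input on the opposite allele leaves the estimate unchanged."""
        for pufa, exp in instruments_by_pufa.items():
            base = ivw_fixed(harmonized(exp, scz_outcome))
            for i, rec in enumerate(exp):
                if rec.other_allele is None:
                    continue
                flipped_exp = list(exp)
                flipped_exp[i] = rec.flipped()
                alt = ivw_fixed(harmonized(flipped_exp, scz_outcome))
                assert alt.beta == pytest.approx(base.beta, abs=1e-14)
                assert alt.se == pytest.approx(base.se, abs=1e-14)


class TestFStatistic:
    def test_direct_arithmetic(self):
        a = assoc(beta=1.0, se=0.1, maf=0.1, n=1000)
        res = f_statistic(a, k=1)
        assert res.r_squared == pytest.approx(0.18)
        assert res.f == pytest.approx(998 * 0.18 / 0.82, rel=1e-12)
        assert not res.weak

    def test_zero_beta(self):
        res = f_statistic(assoc(beta=0.0, se=0.1, maf=0.2, n=100), k=1)
        assert res.r_squared == 0.0 and res.f == 0.0 and res.weak

    def test_closed_form_unit_f(self):
        res = f_statistic(assoc(beta=1.0, se=0.1, maf=0.5, n=3), k=1)
        assert res.r_squared == pytest.approx(0.5)
        assert res.f == pytest.approx(1.0)

    def test_inconsistent_units_rejected(self):
        with pytest.raises(DomainError):
            f_statistic(assoc(beta=10.0, se=0.1, maf=0.5, n=100), k=1)

    @given(
        st.floats(0.05, 0.5),
        st.floats(0.01, 1.2),
        st.floats(0.02, 0.2),
        st.integers(50, 5000),
    )
    def test_monotone_in_beta_and_n(self, maf, b1, db, n):
        f_lo = f_statistic(assoc(beta=b1, se=0.1, maf=maf, n=n), k=1).f
        f_hi = f_statistic(assoc(beta=b1 + db, se=0.1, maf=maf, n=n), k=1).f
        assert f_hi > f_lo
        f_more_n = f_statistic(assoc(beta=b1, se=0.1, maf=maf, n=n + 100), k=1).f
        assert f_more_n > f_lo


class TestReport:
    def test_aa_forest_rows(self, instruments_by_pufa, scz_outcome):
        inst = harmonized(instruments_by_pufa["AA"], scz_outcome)
        est = ivw_fixed(inst)
        df = mr_report("AA", inst, est)
        assert len(df) == 3
        assert set(df["snp"]) == {"rs174547", "rs16966952", "IVW (pooled)"}
        assert df[df.snp == "IVW (pooled)"]["or"].iloc[0] == pytest.approx(0.986,
                                                                           abs=0.001)
        # both AA instruments drive the effect in the same (protective) direction
        per_snp = df[df.snp != "IVW (pooled)"]
        assert (per_snp["or"] < 1.0).all()

    def test_single_instrument_report(self, instruments_by_pufa, scz_outcome):
        inst = harmonized(instruments_by_pufa["DHA"], scz_outcome)
        est = ivw_fixed(inst)
        df = mr_report("DHA", inst, est)
        assert len(df) == 2
        assert df["or"].iloc[0] == pytest.approx(df["or"].iloc[1], rel=1e-12)


def test_univariable_mr_runs_all_eight_pufas(instruments_by_pufa, scz_outcome):
    estimates, forest = univariable_mr(instruments_by_pufa, scz_outcome)
    assert len(estimates) == 8
    assert set(estimates["exposure"]) == set(instruments_by_pufa)
    # forest has one row per instrument plus one pooled row per exposure
    n_instruments = sum(len(v) for v in instruments_by_pufa.values())
    assert len(forest) == n_instruments + 8
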