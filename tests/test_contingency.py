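"""Count-table statistics: chi-square, Fisher, OR/RR intervals, HWE."""

import math

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.stats import hypergeom

from gxepi import (TwoByTwoTable, fisher_exact, hwe_test, odds_ratio,
                   pearson_chi2, risk_ratio)
from gxepi.contingency import DegenerateTableError

# deterministic hypothesis profile: derandomize for reproducible CI runs
settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")

tables = st.tuples(st.integers(1, 40), st.integers(1, 40),
                   st.integers(1, 40), st.integers(1, 40))


class TestPearsonChi2:
    @pytest.mark.parametrize("table, expected", [
        ([[16, 12], [23, 62]], 8.434),
        ([[36, 67], [23, 62]], 1.347),
    ])
    def test_exposure_association_statistics(self, table, expected):
        res = pearson_chi2(table)
        assert res.statistic == pytest.approx(expected, abs=5e-4)
        assert res.df == 1

    def test_proportional_rows_give_zero(self):
        assert pearson_chi2([[10, 20], [5, 10]]).statistic == pytest.approx(0)

    def test_degenerate_margin_errors(self):
        with pytest.raises(DegenerateTableError):
            pearson_chi2([[0, 0], [5, 10]])

    def test_yates_correction_shrinks_statistic(self):
        t = [[16, 12], [23, 62]]
        assert pearson_chi2(t, correction=True).statistic \
            < pearson_chi2(t).statistic

    @given(tables, st.integers(2, 5))
    def test_statistic_scales_linearly_in_counts(self, cells, k):
        t = [[cells[0], cells[1]], [cells[2], cells[3]]]
        tk = [[k * x for x in row] for row in t]
        assert pearson_chi2(tk).statistic == pytest.approx(
            k * pearson_chi2(t).statistic, rel=1e-9)


def fisher_enumeration(table: TwoByTwoTable) -> float:
    """Oracle: exhaustive hypergeometric enumeration of the two-sided p."""
    a, b, c, d = table.cells
    r1, c1, n = a + b, a + c, a + b + c + d
    p_obs = hypergeom.pmf(a, n, r1, c1)
    total = 0.0
    for k in range(max(0, r1 + c1 - n), min(r1, c1) + 1):
        pk = hypergeom.pmf(k, n, r1, c1)
        if pk <= p_obs * (1 + 1e-9):
            total += pk
    return min(total, 1.0)


class TestFisherExact:
    def test_perfectly_discordant_table(self):
        assert fisher_exact(TwoByTwoTable(0, 5, 5, 0)) \
            == pytest.approx(2 / 252, rel=1e-9)

    def test_symmetric_table(self):
        assert fisher_exact(TwoByTwoTable(1, 1, 1, 1)) == pytest.approx(1.0)

    @given(st.tuples(st.integers(0, 10), st.integers(0, 10),
                     st.integers(0, 10), st.integers(0, 10))
           .filter(lambda t: 0 < sum(t) <= 30))
    def test_matches_enumeration_oracle_small_tables(self, cells):
        t = TwoByTwoTable(*cells)
        assert fisher_exact(t) == pytest.approx(fisher_enumeration(t),
                                                rel=1e-7)


class TestOddsRatio:
    def test_ets_combined_phenotype(self):
        est = odds_ratio(TwoByTwoTable(16, 12, 23, 62))
        assert est.point == pytest.approx(3.59, abs=5e-3)
        assert est.ci_low == pytest.approx(1.48, abs=5e-3)
        assert est.ci_high == pytest.approx(8.74, abs=5e-3)

    def test_exposed_stratum_cross_product(self):
        est = odds_ratio(TwoByTwoTable(24, 8, 12, 34))
        assert est.point == pytest.approx(8.50, abs=5e-3)
        assert est.ci_low == pytest.approx(3.02, abs=5e-3)
        assert est.ci_high == pytest.approx(23.95, abs=5e-3)

    def test_symmetric_table_is_null(self):
        assert odds_ratio(TwoByTwoTable(5, 5, 5, 5)).point == pytest.approx(1.0)

    def test_zero_cell_continuity_policy(self):
        est = odds_ratio(TwoByTwoTable(0, 5, 5, 5))
        assert "continuity_corrected" in est.flags
        assert est.point == pytest.approx((0.5 * 5.5) / (5.5 * 5.5))

    def test_double_zero_cells_stay_finite_after_correction(self):
        # the +0.5-everywhere policy keeps even a doubly-degenerate table
        # estimable; the corrected cross-product is (5.5*5.5)/(0.5*0.5)
        est = odds_ratio(TwoByTwoTable(5, 0, 0, 5))
        assert math.isfinite(est.point)
        assert est.point == pytest.approx(121.0)
        assert "continuity_corrected" in est.flags

    @given(tables)
    def test_transpose_symmetry(self, cells):
        t = TwoByTwoTable(*cells)
        assert odds_ratio(t.transpose()).point \
            == pytest.approx(odds_ratio(t).point, rel=1e-12)

    @given(tables, st.integers(2, 9))
    def test_row_scaling_invariance(self, cells, k):
        a, b, c, d = cells
        assert odds_ratio(TwoByTwoTable(k * a, k * b, c, d)).point \
            == pytest.approx(odds_ratio(TwoByTwoTable(a, b, c, d)).point,
                             rel=1e-12)

    @given(tables)
    def test_ci_brackets_point_and_narrows_with_alpha(self, cells):
        t = TwoByTwoTable(*cells)
        wide = odds_ratio(t, alpha=0.05)
        narrow = odds_ratio(t, alpha=0.20)
        assert wide.ci_low <= wide.point <= wide.ci_high
        assert narrow.ci_low >= wide.ci_low
        assert narrow.ci_high <= wide.ci_high


class TestRiskRatio:
    @pytest.mark.parametrize("table, expected", [
        ((24, 12, 14, 62), 3.62),   # effect-allele/exposed vs reference
        ((20, 13, 8, 42), 3.79),
    ])
    def test_joint_category_ratios(self, table, expected):
        assert risk_ratio(TwoByTwoTable(*table)).point \
            == pytest.approx(expected, abs=5e-3)

    def test_identical_risks(self):
        assert risk_ratio(TwoByTwoTable(4, 6, 8, 12)).point \
            == pytest.approx(1.0)

    def test_not_transpose_symmetric(self):
        t = TwoByTwoTable(20, 13, 8, 42)
        assert risk_ratio(t.transpose()).point \
            != pytest.approx(risk_ratio(t).point)


class TestHwe:
    def test_control_genotypes(self):
        res = hwe_test((24, 48, 13))
        assert res.statistic == pytest.approx(1.878, abs=5e-4)
        assert res.df == 1

    def test_exact_equilibrium(self):
        assert hwe_test((25, 50, 25)).statistic == pytest.approx(0.0)

    def test_second_snp_against_direct_formula(self):
        obs = (20, 35, 30)
        n = sum(obs)
        q = (2 * obs[2] + obs[1]) / (2 * n)
        exp = (n * (1 - q) ** 2, 2 * n * q * (1 - q), n * q ** 2)
        direct = sum((o - e) ** 2 / e for o, e in zip(obs, exp))
        assert hwe_test(obs).statistic == pytest.approx(direct, rel=1e-12)

    def test_monomorphic_sample(self):
        res = hwe_test((50, 0, 0))
        assert res.p_value == 1.0
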