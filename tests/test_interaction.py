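"""Joint-classification tables, stratified effects, RERI/AP/S measures."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from gxepi import (ASTHMA_ECZEMA_VS_CONTROL, NRXN1, TNS1,
                   JointClassificationTable, Phenotype, SimConfig,
                   interaction_measures, joint_classification,
                   simulate_joint_table, stratified_effects)
from gxepi.interaction import interaction_wald_from_cells

settings.register_profile("default", derandomize=True, deadline=None)
settings.load_profile("default")


def jt_of(cases, controls, snp=TNS1):
    return JointClassificationTable(snp=snp, cases=cases, controls=controls)


class TestJointClassification:
    def test_published_allele_counts(self, study_records):
        jt = joint_classification(study_records, TNS1,
                                  ASTHMA_ECZEMA_VS_CONTROL)
        assert jt.cases == (14, 10, 8, 24)
        assert jt.controls == (62, 62, 34, 12)
        jt2 = joint_classification(study_records, NRXN1,
                                   ASTHMA_ECZEMA_VS_CONTROL)
        assert jt2.cases == (8, 16, 12, 20)
        assert jt2.controls == (42, 82, 33, 13)

    def test_case_total_is_twice_case_children(self, study_records):
        jt = joint_classification(study_records, TNS1,
                                  ASTHMA_ECZEMA_VS_CONTROL)
        n_case_children = sum(
            1 for r in study_records
            if r.phenotype is Phenotype.ECZEMA_ASTHMA and
            r.exposure is not None and r.genotype(TNS1) is not None)
        assert sum(jt.cases) == 2 * n_case_children

    def test_no_exposed_participants_fatal(self, study_records):
        unexposed = [r for r in study_records if r.exposure is False]
        with pytest.raises(ValueError, match="no exposed"):
            joint_classification(unexposed, TNS1, ASTHMA_ECZEMA_VS_CONTROL)


class TestStratifiedEffects:
    @pytest.mark.parametrize("snp, exposed_or, unexposed_or", [
        (TNS1, 8.50, 0.71),
        (NRXN1, 4.23, 1.02),
    ])
    def test_published_stratum_ratios(self, study_records, snp, exposed_or,
                                      unexposed_or):
        strat = stratified_effects(study_records, snp,
                                   ASTHMA_ECZEMA_VS_CONTROL)
        assert strat["exposed"].point == pytest.approx(exposed_or, abs=5e-3)
        assert strat["unexposed"].point == pytest.approx(unexposed_or,
                                                         abs=5e-3)

    def test_exposed_stratum_woolf_interval(self, study_records):
        strat = stratified_effects(study_records, TNS1,
                                   ASTHMA_ECZEMA_VS_CONTROL)
        assert strat["exposed"].ci_low == pytest.approx(3.02, abs=5e-3)
        assert strat["exposed"].ci_high == pytest.approx(23.95, abs=5e-3)


class TestInteractionMeasures:
    def test_tns1_panel(self, study_records):
        jt = joint_classification(study_records, TNS1,
                                  ASTHMA_ECZEMA_VS_CONTROL)
        res = interaction_measures(jt, measure="risk_ratio")
        pts = [e.point for e in res.category_estimates[1:]]
        assert pts == pytest.approx([0.75, 1.03, 3.62], abs=5e-3)
        assert round(res.ap, 2) == 0.78
        assert res.synergy_index is None
        assert "undefined" in res.synergy_note
        assert res.interaction_p < 0.001

    def test_nrxn1_panel(self, study_records):
        jt = joint_classification(study_records, NRXN1,
                                  ASTHMA_ECZEMA_VS_CONTROL)
        res = interaction_measures(jt, measure="risk_ratio")
        pts = [e.point for e in res.category_estimates[1:]]
        assert pts == pytest.approx([1.02, 1.67, 3.79], abs=5e-3)
        assert round(res.ap, 2) == 0.55
        assert res.synergy_index is not None and res.synergy_index > 1
        assert res.interaction_p == pytest.approx(0.037, abs=5e-3)

    def test_paper_rounding_concordance_mode(self, study_records):
        # rounded 2-dp category inputs reproduce report-style RERI values
        jt = joint_classification(study_records, TNS1,
                                  ASTHMA_ECZEMA_VS_CONTROL)
        rounded = interaction_measures(jt, input_decimals=2)
        exact = interaction_measures(jt)
        assert rounded.reri == pytest.approx(2.84, abs=1e-9)
        assert exact.reri == pytest.approx(2.831, abs=5e-4)

    def test_additive_null_gives_zero_reri(self):
        # category risks 0.5, 0.75, 0.6, 0.85 -> RR 1.5, 1.2, 1.7 with
        # RR11 = RR10 + RR01 - 1 exactly
        jt = jt_of((10, 15, 12, 17), (10, 5, 8, 3))
        res = interaction_measures(jt, measure="risk_ratio")
        assert res.reri == pytest.approx(0.0, abs=1e-12)
        assert res.ap == pytest.approx(0.0, abs=1e-12)

    def test_multiplicative_null_gives_unit_ratio(self):
        # equal stratum cross-product ratios -> product term exactly 0
        jt = jt_of((10, 20, 30, 60), (10, 10, 10, 10))
        res = interaction_measures(jt, measure="odds_ratio")
        assert res.ratio_of_rr == pytest.approx(1.0, rel=1e-12)
        beta, _, _ = interaction_wald_from_cells(jt.cells)
        assert beta == pytest.approx(0.0, abs=1e-12)

    def test_empty_reference_fatal(self):
        jt = jt_of((0, 15, 12, 17), (10, 5, 8, 3))
        with pytest.raises(ValueError, match="reference"):
            interaction_measures(jt)

    cells8 = st.tuples(*[st.integers(1, 60)] * 8)

    @given(cells8)
    def test_reri_identity_holds_exactly(self, cells):
        jt = jt_of(cells[:4], cells[4:])
        res = interaction_measures(jt, measure="risk_ratio")
        r10, r01, r11 = (e.point for e in res.category_estimates[1:])
        assert res.reri + r10 + r01 - 1 == pytest.approx(r11, rel=1e-12)

    @given(cells8)
    def test_ap_bounds_and_sign_linkage(self, cells):
        jt = jt_of(cells[:4], cells[4:])
        res = interaction_measures(jt, measure="risk_ratio")
        r10, r01, _ = (e.point for e in res.category_estimates[1:])
        if r10 + r01 >= 1:
            # AP = 1 - (RR10 + RR01 - 1)/RR11 can only exceed 1 when both
            # single-factor effects are jointly protective
            assert res.ap <= 1 + 1e-12
        assert (res.ap > 0) == (res.reri > 0)

    @given(cells8)
    def test_ci_brackets_reri_and_ap(self, cells):
        jt = jt_of(cells[:4], cells[4:])
        res = interaction_measures(jt)
        assert res.reri_ci[0] <= res.reri <= res.reri_ci[1]
        assert res.ap_ci[0] <= res.ap <= res.ap_ci[1]


class TestAdditiveNullCalibration:
    def test_mean_reri_unbiased_under_global_null(self):
        # with no genetic, exposure or product effect every category RR
        # is 1 in expectation, so RERI must average to ~0 at large n
        cfg = SimConfig(beta_g=0.0, beta_e=0.0, beta_ge=0.0,
                        n_cases=5000, n_controls=5000)
        reris = []
        for jt in simulate_joint_table(cfg, n_reps=400, seed=202):
            res = interaction_measures(jt, measure="risk_ratio")
            reris.append(res.reri)
        reris = np.array(reris)
        mc_se = reris.std(ddof=1) / np.sqrt(len(reris))
        assert abs(reris.mean()) < 3 * mc_se
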