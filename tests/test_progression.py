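"""Clinical transition probabilities, modifiers and mortality."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hkcea.progression import (apply_modifier, ckd_transition_matrix,
                               ckd_transition_probs, combined_event_prob,
                               death_prob_grids, esrd_params_for_age,
                               event_prob_grids, mortality_prob,
                               nyha_transition_matrix)
from hkcea.states import CKDState, RAASiStatus

from conftest import immortal


class TestEsrdAgeRule:
    @pytest.mark.parametrize("age,field,expected", [
        (40, "transplant_from_ckd5", 0.0215),
        (50, "transplant_from_ckd5", 0.0168),
        (70, "death_on_dialysis", 0.0123),
        (40, "death_on_dialysis", 0.0018),
        (70, "death_with_transplant", 0.0055),
        (60, "transplant_from_dialysis", 0.0006),
    ])
    def test_exact_at_knots(self, fixture_params, age, field, expected):
        block = esrd_params_for_age(age, fixture_params)
        assert getattr(block, field) == expected

    def test_step_rule_holds_value_from_knot_below(self, fixture_params):
        at65 = esrd_params_for_age(65, fixture_params)
        at60 = esrd_params_for_age(60, fixture_params)
        assert at65 == at60

    def test_clamped_outside_span(self, fixture_params):
        assert esrd_params_for_age(30, fixture_params) == \
            esrd_params_for_age(40, fixture_params)
        assert esrd_params_for_age(95, fixture_params) == \
            esrd_params_for_age(70, fixture_params)

    def test_linear_rule_interpolates(self, fixture_params):
        p = fixture_params.model_copy(deep=True)
        p.esrd.rule = "linear"
        mid = esrd_params_for_age(45, p)
        assert mid.transplant_from_ckd5 == pytest.approx((0.0215 + 0.0168) / 2)


class TestModifiers:
    def test_rate_scale_closed_form(self):
        assert apply_modifier(0.10, 0.5) == pytest.approx(1 - 0.9**0.5)
        assert apply_modifier(0.10, 0.5) == pytest.approx(0.05131670, abs=1e-7)

    @settings(deadline=None, derandomize=True)
    @given(p=st.floats(0.0, 0.999), hr=st.floats(0.01, 10.0))
    def test_modifier_properties(self, p, hr):
        out = apply_modifier(p, hr)
        assert 0.0 <= out < 1.0
        assert apply_modifier(p, 1.0) == pytest.approx(p)
        assert apply_modifier(0.0, hr) == 0.0
        if hr > 1:
            assert out >= p - 1e-15
        else:
            assert out <= p + 1e-12

    def test_combined_event_prob_is_max(self):
        assert combined_event_prob(0.03, 0.05) == 0.05
        assert combined_event_prob(0.07, 0.07) == 0.07
        assert combined_event_prob(0.0, 0.2) == 0.2


class TestMortality:
    def test_life_table_conversion(self, fixture_params):
        # annual q = 0.0237 -> monthly 1-(0.9763)^(1/12)
        expected = 1 - 0.9763 ** (1 / 12)
        assert expected == pytest.approx(0.0019968, abs=1e-6)
        p = fixture_params.model_copy(deep=True)
        n = len(p.life_table.ages)
        p.life_table.qx_female = [0.0237] * n
        p.life_table.qx_male = [0.0237] * n
        assert p.life_table.monthly_q(70, 0.46) == pytest.approx(expected)

    def test_max_rule(self, fixture_params):
        p = fixture_params.model_copy(deep=True)
        n = len(p.life_table.ages)
        p.life_table.qx_female = [0.0237] * n
        p.life_table.qx_male = [0.0237] * n
        floor = p.life_table.monthly_q(70, 0.46)
        assert mortality_prob(0.001, 70, p) == pytest.approx(floor)
        assert mortality_prob(0.004, 70, p) == 0.004

    def test_monotone_in_both_arguments(self, fixture_params):
        p = fixture_params
        base = mortality_prob(0.002, 70, p)
        assert mortality_prob(0.003, 70, p) >= base
        assert mortality_prob(0.002, 85, p) >= base  # life-table q grows

    def test_death_grid_floor_applied_everywhere(self, fixture_params):
        dc, dh = death_prob_grids(fixture_params, 80.0)
        floor = fixture_params.life_table.monthly_q(
            80.0, fixture_params.demographics.proportion_female.mean)
        assert dc.min() >= floor
        assert dh.min() >= floor


class TestTransitionMatrices:
    def test_rows_sum_to_one(self, fixture_params):
        mat = ckd_transition_matrix(65.3, fixture_params)
        np.testing.assert_allclose(mat.sum(axis=2), 1.0, atol=1e-12)
        nyha = nyha_transition_matrix(fixture_params)
        np.testing.assert_allclose(nyha.sum(axis=1), 1.0, atol=1e-12)

    def test_ckd5_transplant_from_table(self, fixture_params):
        probs = ckd_transition_probs(CKDState.CKD5, 40,
                                     RAASiStatus.MAX_DOSE, fixture_params)
        assert probs[CKDState.TRANSPLANT] == 0.0215

    def test_identity_modifier_reproduces_baseline(self, fixture_params):
        p = fixture_params.model_copy(deep=True)
        for m in p.modifiers.raasi.ckd_progression.values():
            m.mean = 1.0
        mat = ckd_transition_matrix(65.3, p)
        np.testing.assert_array_equal(mat[0], mat[2])
        assert mat[0][CKDState.CKD3, CKDState.CKD4] \
            == pytest.approx(p.ckd.prog_3_to_4.mean)

    def test_no_ckd_regression(self, fixture_params):
        mat = ckd_transition_matrix(65.3, fixture_params)
        assert np.all(np.tril(mat[0], k=-1) == 0.0)

    def test_inconsistent_config_raises(self, fixture_params):
        p = fixture_params.model_copy(deep=True)
        p.ckd.prog_5_to_dialysis.mean = 0.999
        with pytest.raises(ValueError, match="CKD5"):
            ckd_transition_matrix(40, p)  # + transplant 2.15% pushes sum > 1

    def test_pure_chain_matches_matrix_power_oracle(self, fixture_params):
        """With all modifiers at 1 and ESRD/death off, occupancy follows the
        baseline chain exactly (direct matrix-power oracle)."""
        from hkcea import run_cohort
        from conftest import no_esrd
        p = no_esrd(immortal(fixture_params))
        for group in (p.modifiers.raasi.ckd_progression,
                      p.modifiers.raasi.death):
            for m in group.values():
                m.mean = 1.0
        p34, p45 = p.ckd.prog_3_to_4.mean, p.ckd.prog_4_to_5.mean
        M = np.array([[1 - p34, p34, 0], [0, 1 - p45, p45], [0, 0, 1]])
        v0 = np.array([p.start.ckd3.mean, p.start.ckd4.mean, 0.0])
        n = 60
        res = run_cohort("soc", p, horizon_age=p.demographics.age_years.mean
                         + (n + 0.5) / 12)
        assert res.n_cycles == n + 1
        np.testing.assert_allclose(res.alive, 1.0, atol=1e-12)
        for cycle in (1, 10, n):
            expected = v0 @ np.linalg.matrix_power(M, cycle)
            np.testing.assert_allclose(res.ckd_occupancy[cycle, :3],
                                       expected, atol=1e-12)
            np.testing.assert_allclose(res.ckd_occupancy[cycle, 3:], 0.0)


class TestEventGrids:
    def test_hf_grid_uses_max_rule(self, fixture_params):
        mc, mh = event_prob_grids(fixture_params, 65.3, "mace")
        base_ckd3 = fixture_params.ckd.mace["ckd3"].mean
        base_n4 = fixture_params.hf.mace["nyha4"].mean
        # NYHA IV dominates CKD3 baseline
        assert mh[0, 3, 0, 0] == pytest.approx(max(base_ckd3, base_n4))
        # CKD dialysis dominates NYHA I
        base_dial = fixture_params.ckd.mace["dialysis"].mean
        assert mh[3, 0, 0, 0] == pytest.approx(
            max(base_dial, fixture_params.hf.mace["nyha1"].mean))

    def test_modifiers_increase_event_probs(self, fixture_params):
        mc, _ = event_prob_grids(fixture_params, 65.3, "mace")
        assert np.all(mc[:, 3, :] >= mc[:, 0, :])   # K>6 vs normokalaemia
        assert np.all(mc[:, :, 2] >= mc[:, :, 0])   # discontinued vs max
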