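"""Cohort engine behaviour and the microsimulation oracle."""

import numpy as np
import pytest

from hkcea import run_cohort, run_microsimulation
from hkcea.engine import EVENT_KINDS, TrajectoryResult, events_per_1000

from conftest import immortal, microsim_se


def _everyone_dies_immediately(p):
    q = p.model_copy(deep=True)
    n = len(q.life_table.ages)
    q.life_table.qx_female = [1.0] * n
    q.life_table.qx_male = [1.0] * n
    return q


def _utopia(p):
    """No events, utility 1 everywhere, no disease mortality, no discounting."""
    q = immortal(p)
    for group in (q.ckd.mace, q.ckd.hospitalisation, q.hf.mace,
                  q.hf.hospitalisation):
        for param in group.values():
            param.mean = 0.0
    for param in q.utilities.state.values():
        param.mean = 1.0
    for param in (q.utilities.disutility_hk.k_5_55,
                  q.utilities.disutility_hk.k_55_6,
                  q.utilities.disutility_hk.k_gt6,
                  q.utilities.disutility_mace,
                  q.utilities.disutility_hospitalisation):
        param.mean = 0.0
    q.settings.discount_rate_annual = 0.0
    return q


class TestLimits:
    def test_forced_death_gives_one_cycle(self, fixture_params):
        res = run_cohort("soc", _everyone_dies_immediately(fixture_params))
        assert res.n_cycles == 1
        assert res.total_ly(False) == pytest.approx(1 / 12)
        assert res.total_qaly(False) <= res.total_ly(False)

    def test_identity_limit_qaly_equals_ly_equals_horizon(self, fixture_params):
        p = _utopia(fixture_params)
        res = run_cohort("soc", p)
        start = p.demographics.age_years.mean
        expected_cycles = int(np.ceil((p.settings.horizon_age - start) * 12))
        assert res.n_cycles == expected_cycles
        assert res.total_ly(False) == pytest.approx(expected_cycles / 12)
        assert res.total_qaly(False) == pytest.approx(res.total_ly(False),
                                                      abs=1e-9)

    def test_no_discount_flag_reproduces_undiscounted(self, fixture_params):
        res = run_cohort("patiromer", fixture_params, discount=False)
        assert res.total_ly(True) == res.total_ly(False)
        assert res.total_cost(True) == res.total_cost(False)


class TestInvariants:
    def test_mass_conserved_every_cycle(self, base_runs):
        for res in base_runs:
            np.testing.assert_allclose(res.alive + res.dead, 1.0, atol=1e-12)

    def test_alive_mass_non_increasing_dead_absorbing(self, base_runs):
        for res in base_runs:
            assert np.all(np.diff(res.alive) <= 1e-15)
            assert np.all(np.diff(res.dead) >= -1e-15)

    def test_discounted_never_exceeds_undiscounted(self, base_runs):
        for res in base_runs:
            assert res.total_ly(True) <= res.total_ly(False)
            assert res.total_qaly(True) <= res.total_qaly(False)
            for cat in res.cost_disc:
                assert res.cost_disc[cat].sum() \
                    <= res.cost_undisc[cat].sum() + 1e-12

    def test_qaly_never_exceeds_ly(self, base_runs):
        for res in base_runs:
            assert res.total_qaly(True) <= res.total_ly(True)
            assert res.total_qaly(False) <= res.total_ly(False)

    def test_binder_reduces_hyperkalaemia_burden(self, base_runs):
        pat, soc = base_runs
        assert pat.total_events("hk_55_6") <= soc.total_events("hk_55_6")
        assert pat.total_events("hk_gt6") <= soc.total_events("hk_gt6")

    def test_half_cycle_correction_is_small_and_downward(self, fixture_params):
        p = fixture_params.model_copy(deep=True)
        p.settings.half_cycle_correction = True
        corrected = run_cohort("soc", p)
        plain = run_cohort("soc", fixture_params)
        assert corrected.total_ly(True) < plain.total_ly(True)
        assert plain.total_ly(True) - corrected.total_ly(True) \
            == pytest.approx(0.5 / 12, abs=1e-9)


class TestEventArithmetic:
    def test_events_per_1000_hand_oracle(self):
        """Two hand-built 2-cycle trajectories with known event masses."""
        def mk(arm, events):
            z = np.zeros(2)
            return TrajectoryResult(
                arm=arm, ages=np.array([65.0, 65 + 1 / 12]),
                alive=np.ones(2), dead=z.copy(), on_treatment=z.copy(),
                ckd_occupancy=np.zeros((2, 5)),
                events={k: np.array(events.get(k, [0, 0]), dtype=float)
                        for k in EVENT_KINDS},
                cost_undisc={}, cost_disc={}, ly_undisc=z, ly_disc=z,
                qaly_undisc=z, qaly_disc=z)
        a = mk("patiromer", {"hk_55_6": [0.10, 0.05]})
        b = mk("soc", {"hk_55_6": [0.25, 0.12]})
        assert events_per_1000(a, b, "hk_55_6") \
            == pytest.approx(1000 * (0.37 - 0.15))
        assert events_per_1000(a, a, "hk_55_6") == 0.0


class TestMicrosimulation:
    def test_same_seed_is_bit_identical(self, fixture_params):
        m1 = run_microsimulation("patiromer", fixture_params, 500, seed=9)
        m2 = run_microsimulation("patiromer", fixture_params, 500, seed=9)
        assert m1.total_cost() == m2.total_cost()
        np.testing.assert_array_equal(m1.individual["ly"],
                                      m2.individual["ly"])

    def test_degenerate_probabilities_match_cohort(self, fixture_params):
        """With all transition randomness removed (no events, no death, one
        starting state) a single simulated individual reproduces the cohort
        trajectory exactly."""
        p = _utopia(fixture_params)
        p.start.hf_share.mean = 0.0
        p.start.ckd3.mean, p.start.ckd4.mean = 1.0, 0.0
        p.ckd.prog_3_to_4.mean = 0.0
        for triple in (p.hk.month1, p.hk.months2_3_soc,
                       p.hk.subsequent_soc):
            for name in ("k_5_55", "k_55_6", "k_gt6"):
                getattr(triple, name).mean = 0.0
        p.start.k_55_6.mean, p.start.k_gt6.mean = 0.0, 0.0
        p.start.k_le5.mean = 1.0
        for rates in (p.raasi.months2_3_soc, p.raasi.subsequent_soc.k_le5):
            rates.discontinue_from_max.mean = 0.0
            rates.down_titrate_from_max.mean = 0.0
        cohort = run_cohort("soc", p, horizon_age=70.0)
        micro = run_microsimulation("soc", p, 1, seed=1, horizon_age=70.0)
        assert micro.total_ly(False) == pytest.approx(cohort.total_ly(False))
        assert micro.total_cost() == pytest.approx(cohort.total_cost())

    def test_cohort_within_monte_carlo_error(self, fixture_params):
        """Cohort expectations agree with a seeded 20k-individual
        microsimulation within 3 standard errors on the core outcomes (the
        full 100k check runs in the acceptance suite)."""
        n = 20_000
        micro = run_microsimulation("patiromer", fixture_params, n, seed=17)
        cohort = run_cohort("patiromer", fixture_params)
        for key, value in (("ly", cohort.total_ly(True)),
                           ("qaly", cohort.total_qaly(True)),
                           ("cost", cohort.total_cost(True))):
            mean = micro.individual[key].mean()
            se = microsim_se(micro, key)
            assert abs(mean - value) < 3 * se, key
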