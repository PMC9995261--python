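"""Parameter schema, fixture provenance, sampling and validation."""

import json

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hkcea import (load_parameters, make_reference_fixture, sample_parameters,
                   save_parameters, validate_parameters)
from hkcea.parameters import Param, SamplingError, get_param, iter_params

from conftest import fix_all


class TestReferenceFixture:
    def test_main_text_values(self, fixture_params):
        p = fixture_params
        assert p.start.hf_share.mean == 0.4198
        assert p.start.ckd3.mean == 0.5514
        assert p.demographics.age_years.mean == 65.30
        assert p.treatment.response.mean == 0.6093
        assert p.treatment.monthly_discontinuation.mean == 0.1033
        assert p.raasi.return_to_optimal.mean == 0.0351
        assert p.settings.discount_rate_annual == 0.035

    def test_hk_event_costs(self, fixture_params):
        costs = fixture_params.costs.hk_event
        assert costs.k_5_55.mean == 0.0
        assert costs.k_55_6.mean == 223.11
        assert costs.k_gt6.mean == 2933.49

    def test_month1_hk_identical_across_arms(self, fixture_params):
        # month-1 incidence applies before any treatment effect can differ
        m1 = fixture_params.hk.month1.means()
        np.testing.assert_array_equal(m1, [0.2113, 0.0166, 0.0038])

    def test_fixture_passes_validation(self, fixture_params):
        assert validate_parameters(fixture_params) == []

    def test_placeholders_are_flagged(self, fixture_params):
        provenances = {param.provenance
                       for _, param in iter_params(fixture_params)}
        assert "supplementary-placeholder" in provenances
        assert get_param(fixture_params, "ckd.prog_3_to_4").provenance \
            == "supplementary-placeholder"
        assert get_param(fixture_params, "start.hf_share").provenance \
            == "paper-main-text"


class TestValidation:
    def test_utility_above_one_is_flagged(self, fixture_params):
        p = fixture_params.model_copy(deep=True)
        p.utilities.state["ckd3"].mean = 1.2
        violations = validate_parameters(p)
        assert len(violations) == 1
        assert "ckd3" in violations[0].field

    def test_negative_probability_names_the_cell(self, fixture_params):
        p = fixture_params.model_copy(deep=True)
        p.hk.subsequent_soc.k_gt6.mean = -0.01
        violations = validate_parameters(p)
        assert any("subsequent_soc.k_gt6" in v.field for v in violations)

    def test_from_max_rates_summing_above_one_flagged(self, fixture_params):
        p = fixture_params.model_copy(deep=True)
        p.raasi.months2_3_soc.discontinue_from_max.mean = 0.7
        violations = validate_parameters(p)
        assert any("months2_3_soc" in v.field for v in violations)


class TestIO:
    def test_round_trip_is_value_identical(self, fixture_params, tmp_path):
        for suffix in (".yaml", ".json"):
            path = tmp_path / f"config{suffix}"
            save_parameters(fixture_params, path)
            loaded = load_parameters(path)
            assert loaded.model_dump() == fixture_params.model_dump()

    def test_partial_file_filled_from_fixture(self, tmp_path):
        path = tmp_path / "partial.yaml"
        path.write_text("demographics:\n  age_years:\n    mean: 70.0\n"
                        "    se: 0.0\n    family: normal\n")
        p = load_parameters(path)
        assert p.demographics.age_years.mean == 70.0
        # omitted utilities come from the fixture, flags preserved
        assert p.utilities.state["ckd3"].provenance \
            == "supplementary-placeholder"
        assert p.start.hf_share.mean == 0.4198

    def test_inconsistent_distribution_rejected(self, tmp_path):
        path = tmp_path / "bad.yaml"
        path.write_text("start:\n  ckd3: {mean: 0.45, se: 0.0}\n")
        with pytest.raises(ValueError, match="start.ckd"):
            load_parameters(path)

    def test_shipped_schema_parses(self):
        from importlib.resources import files
        schema = json.loads(files("hkcea").joinpath(
            "data/parameter_set.schema.json").read_text())
        assert schema["title"] == "ParameterSet"
        assert "demographics" in schema["properties"]


class TestSampling:
    def test_zero_se_draw_equals_base(self, fixture_params):
        p0 = fix_all(fixture_params)
        draw = sample_parameters(p0, np.random.default_rng(0))
        for (path, a), (_, b) in zip(iter_params(draw), iter_params(p0)):
            assert a.mean == b.mean, path

    def test_beta_moment_matching_closed_form(self):
        # alpha = m(m(1-m)/s^2 - 1), beta = (1-m)(m(1-m)/s^2 - 1)
        m, s = 0.5514, 0.0319
        nu = m * (1 - m) / s**2 - 1
        alpha, beta = m * nu, (1 - m) * nu
        fitted_mean = alpha / (alpha + beta)
        fitted_var = alpha * beta / ((alpha + beta) ** 2 * (alpha + beta + 1))
        assert abs(fitted_mean - m) < 1e-10
        assert abs(fitted_var - s**2) < 1e-10

    @settings(deadline=None, derandomize=True)
    @given(m=st.floats(0.01, 0.99), frac=st.floats(0.05, 0.9))
    def test_moment_matching_recovers_mean_and_se(self, m, frac):
        """For each family the fitted distribution's analytic moments equal
        (mean, se^2) to 1e-9."""
        s = frac * np.sqrt(m * (1 - m)) * 0.999
        nu = m * (1 - m) / s**2 - 1
        a, b = m * nu, (1 - m) * nu
        assert abs(a / (a + b) - m) < 1e-9
        assert abs(a * b / ((a + b) ** 2 * (a + b + 1)) - s * s) < 1e-9
        shape, scale = m * m / (s * s), s * s / m
        assert abs(shape * scale - m) < 1e-9
        assert abs(shape * scale**2 - s * s) < 1e-9

    def test_structural_zeros_stay_zero(self, fixture_params):
        draw = sample_parameters(fixture_params, np.random.default_rng(7))
        assert draw.start.nyha4.mean == 0.0
        assert draw.start.ckd5.mean == 0.0
        assert draw.costs.hk_event.k_5_55.mean == 0.0

    def test_reproducible_across_matched_seeds(self, fixture_params):
        d1 = sample_parameters(fixture_params, np.random.default_rng(42))
        d2 = sample_parameters(fixture_params, np.random.default_rng(42))
        assert d1.model_dump() == d2.model_dump()
        d3 = sample_parameters(fixture_params, np.random.default_rng(43))
        assert d3.model_dump() != d1.model_dump()

    def test_sampled_distributions_remain_valid(self, fixture_params):
        rng = np.random.default_rng(11)
        for _ in range(5):
            draw = sample_parameters(fixture_params, rng)
            assert validate_parameters(draw) == []

    def test_normal_demographic_sampling_is_unbiased(self):
        param = Param(mean=65.30, se=0.89, family="normal")
        rng = np.random.default_rng(5)
        draws = np.array([param.sample(rng) for _ in range(10_000)])
        assert abs(draws.mean() - 65.30) < 3 * 0.89 / np.sqrt(10_000)

    def test_proportion_normal_truncated(self):
        param = Param(mean=0.05, se=0.2, family="normal", bounds=(0.0, 1.0))
        rng = np.random.default_rng(3)
        draws = np.array([param.sample(rng) for _ in range(500)])
        assert draws.min() >= 0.0 and draws.max() <= 1.0

    def test_infeasible_beta_names_parameter(self):
        param = Param(mean=0.001, se=0.5, family="beta")
        with pytest.raises(SamplingError, match="my.field"):
            param.sample(np.random.default_rng(0), "my.field")
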