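"""Configuration loading, defaults and validation."""

import numpy as np
import pytest

from mbs_cua.parameters import (
    ConfigurationError,
    ModelOptions,
    ParameterSet,
    ValidationError,
    default_parameters,
    load_parameters,
)


class TestDefaults:
    def test_point_values(self, params):
        assert params.initial_age == 52.4
        assert params.horizon_cycles == 40
        assert params.discount_rate == 0.05
        assert params.wtp == 64000.0
        np.testing.assert_allclose(
            params.initial_distribution, [0.0, 0.005, 0.200, 0.795]
        )
        assert params.rr_diabetes_mortality == 1.54
        assert params.utilities[3] == 0.550  # class-III utility weight
        assert params.disutility_diabetes == 0.116
        assert params.surgery_cost == {"OB1": 15734.0, "OB2": 15734.0, "OB3": 18242.0}
        np.testing.assert_allclose(
            params.management_cost, [6762.0, 7574.0, 8926.0, 8926.0]
        )
        assert params.diabetes_cost == 3997.0

    def test_year1_rows_sum_to_one(self, params):
        for row in params.year1_surgery_transitions.values():
            assert sum(row.values()) == pytest.approx(1.0, abs=1e-12)

    def test_override_discount_rate(self):
        ps = load_parameters({"use_defaults": True, "discount_rate": 0.03})
        assert ps.discount_rate == 0.03
        assert ps.wtp == 64000.0  # everything else untouched

    def test_all_distributed_parameters_have_specs(self, params):
        assert len(params.distributions) == 17
        for spec in params.distributions.values():
            assert spec.kind in ("beta", "gamma", "triangular", "fixed")


class TestLoadParameters:
    def test_missing_key_named_in_error(self):
        with pytest.raises(ConfigurationError, match="wtp"):
            load_parameters({"initial_age": 50.0})

    def test_unnormalized_initial_distribution_rejected(self):
        with pytest.raises(ValidationError, match="initial_distribution"):
            load_parameters(
                {
                    "use_defaults": True,
                    "initial_distribution": {
                        "OW": 0.5, "OB1": 0.5, "OB2": 0.5, "OB3": 0.5
                    },
                }
            )

    def test_year1_row_sum_violation_rejected(self):
        with pytest.raises(ValidationError, match="year1_surgery_transitions"):
            load_parameters(
                {
                    "use_defaults": True,
                    "year1_surgery_transitions": {"OB1": {"OW": 0.9, "OB1": 0.0}},
                }
            )

    @pytest.mark.parametrize(
        "key, value",
        [
            ("discount_rate", -0.01),
            ("surgical_mortality", 1.5),
            ("horizon_cycles", 0),
            ("diabetes_cost", -1.0),
        ],
    )
    def test_invariant_violations_rejected(self, key, value):
        with pytest.raises(ValidationError, match=key.split("_")[0]):
            load_parameters({"use_defaults": True, key: value})

    def test_load_serialize_reload_is_identity(self, params, tmp_path):
        path = tmp_path / "config.yaml"
        params.to_yaml(path)
        again = load_parameters(path)
        assert again.to_dict() == params.to_dict()

    def test_yaml_file_roundtrip_equals_defaults(self, tmp_path):
        from importlib import resources

        template = resources.files("mbs_cua") / "data" / "default_config.yaml"
        ps = load_parameters(str(template))
        assert ps.to_dict() == default_parameters().to_dict()


class TestAccessorsAndUpdates:
    def test_diabetic_fraction_rules(self, params):
        assert params.diabetic_fraction("UC", 0) == 1.0
        assert params.diabetic_fraction("UC", 20) == 1.0
        assert params.diabetic_fraction("SURGERY", 0) == 1.0  # pre-surgery cohort
        assert params.diabetic_fraction("SURGERY", 1) == 0.101
        assert params.diabetic_fraction("SURGERY", 39) == 0.101

    def test_entry_surgery_cost_weights_entry_classes(self, params):
        expected = 0.005 * 15734 + 0.200 * 15734 + 0.795 * 18242
        assert params.entry_surgery_cost() == pytest.approx(expected)

    def test_effective_horizon_modes(self, params):
        assert params.effective_horizon() == 40
        import dataclasses

        to90 = params.replace(
            options=dataclasses.replace(params.options, horizon_mode="to-age-90")
        )
        assert to90.effective_horizon() == 38  # round(90 - 52.4)
        assert to90.replace(initial_age=30.0).effective_horizon() == 60

    def test_with_value_addresses_pooled_parameters(self, params):
        ps = params.with_value("management_cost_ob2_ob3", 10_000.0)
        assert ps.management_cost[2] == ps.management_cost[3] == 10_000.0
        ps = params.with_value("surgery_cost_ob1_ob2", 20_000.0)
        assert ps.surgery_cost["OB1"] == ps.surgery_cost["OB2"] == 20_000.0
        assert ps.surgery_cost["OB3"] == 18242.0
        with pytest.raises(KeyError):
            params.with_value("no_such_parameter", 1.0)

    def test_options_validation(self):
        with pytest.raises(ValidationError):
            ModelOptions(class_inflator_mode="quadratic")
        with pytest.raises(ValidationError):
            ModelOptions(horizon_mode="forever")
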