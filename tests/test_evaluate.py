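import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from treatbenefit import (
    MarkerSpec,
    SyntheticSpec,
    TrialDataset,
    benefit_distribution,
    bootstrap_performance,
    calibration_table,
    external_validate,
    fit_interaction_model,
    generate_trial,
    multimarker_positivity_rate,
    observed_subgroup_benefit,
    population_impact,
)
from treatbenefit.exceptions import (
    CIError,
    SchemaError,
    UndefinedEstimateError,
)

from conftest import build_reference_model


@pytest.fixture(scope="module")
def micro_fit(micro_trial):
    return fit_interaction_model(micro_trial)


def null_model():
    res = build_reference_model()
    res.params[:] = 0.0
    return res


class TestBenefitDistribution:
    def test_null_model_single_occupied_bin(self, pessary_spec):
        ds = generate_trial(pessary_spec, 200, seed=1)
        preds, edges, counts = benefit_distribution(ds, null_model())
        assert (preds["benefit"] == 0.0).all()
        assert (counts > 0).sum() == 1
        assert counts.sum() == 200

    def test_micro_trial_two_benefit_values(self, micro_trial, micro_fit):
        preds, _, counts = benefit_distribution(micro_trial, micro_fit)
        values = sorted(set(np.round(preds["benefit"], 6)))
        assert values == pytest.approx([-0.10, 0.15], abs=1e-6)
        assert counts.sum() == micro_trial.n

    def test_synthetic_trial_has_mass_on_both_sides_of_zero(
            self, pessary_spec, reference_model):
        ds = generate_trial(pessary_spec, 10_000, seed=6)
        preds, _, _ = benefit_distribution(ds, reference_model)
        assert (preds["benefit"] > 0).any()
        assert (preds["benefit"] < 0).any()

    def test_marker_mismatch_is_schema_error(self, micro_trial):
        with pytest.raises(SchemaError, match="short_cervix"):
            benefit_distribution(micro_trial, build_reference_model())


class TestPositivityRate:
    def test_micro_trial_half_positive(self, micro_trial, micro_fit):
        preds = micro_fit.predict_benefit_frame(micro_trial.markers)
        assert multimarker_positivity_rate(preds) == 0.5

    def test_null_model_all_negative_by_strict_rule(self, pessary_spec):
        ds = generate_trial(pessary_spec, 100, seed=2)
        preds = null_model().predict_benefit_frame(ds.markers)
        assert multimarker_positivity_rate(preds) == 0.0

    def test_uniformly_beneficial_model(self, pessary_spec):
        res = build_reference_model()
        res.params[:] = 0.0
        res.params["treatment"] = -1.0
        ds = generate_trial(pessary_spec, 100, seed=2)
        preds = res.predict_benefit_frame(ds.markers)
        assert multimarker_positivity_rate(preds) == 1.0

    def test_empty_predictions_rejected(self):
        with pytest.raises(ValueError):
            multimarker_positivity_rate(pd.DataFrame(
                {"multimarker_positive": []}))


class TestObservedSubgroupBenefit:
    def test_marker_positive_subgroup(self, micro_trial):
        mask = (micro_trial.markers["x"] == "1").to_numpy()
        assert observed_subgroup_benefit(
            micro_trial, mask, "benefit_of_treatment"
        ) == pytest.approx(0.15)

    def test_marker_negative_subgroup_no_treatment(self, micro_trial):
        mask = (micro_trial.markers["x"] == "0").to_numpy()
        assert observed_subgroup_benefit(
            micro_trial, mask, "benefit_of_no_treatment"
        ) == pytest.approx(0.10)

    def test_directions_are_sign_opposites(self, micro_trial):
        mask = (micro_trial.markers["x"] == "1").to_numpy()
        a = observed_subgroup_benefit(micro_trial, mask,
                                      "benefit_of_treatment")
        b = observed_subgroup_benefit(micro_trial, mask,
                                      "benefit_of_no_treatment")
        assert a == -b

    def test_empty_arm_is_undefined(self, micro_trial):
        mask = (micro_trial.treatment == 0)
        with pytest.raises(UndefinedEstimateError, match="treated"):
            observed_subgroup_benefit(micro_trial, mask)


class TestPopulationImpact:
    def test_micro_trial_treat_none(self, micro_trial, micro_fit):
        s = population_impact(micro_trial, micro_fit)
        assert s.positivity_rate.value == 0.5
        assert s.avg_benefit_positives.value == pytest.approx(0.15)
        assert s.population_impact.value == pytest.approx(0.075)
        assert s.baseline_risk == pytest.approx(40 / 200)
        # exact identities, not approximations
        assert s.population_impact.value == (
            s.positivity_rate.value * s.avg_benefit_positives.value)
        assert s.residual_risk == s.baseline_risk - s.population_impact.value
        assert s.positivity_rate.value + s.negativity_rate == 1.0

    def test_micro_trial_treat_all(self, micro_trial, micro_fit):
        s = population_impact(micro_trial, micro_fit,
                              default_strategy="treat_all")
        assert s.baseline_risk == pytest.approx(35 / 200)
        assert s.population_impact.value == pytest.approx(0.5 * 0.10)
        assert s.population_impact.value == (
            s.negativity_rate
            * s.avg_benefit_no_treatment_negatives.value)

    def test_no_positives_means_zero_impact_with_flag(self, pessary_spec):
        ds = generate_trial(pessary_spec, 100, seed=3)
        s = population_impact(ds, null_model())
        assert s.population_impact.value == 0.0
        assert math.isnan(s.avg_benefit_positives.value)
        assert any("positive" in f for f in s.flags)

    def test_inestimable_subgroup_arm_propagates(self):
        # the single multimarker-positive patient sits in one arm only
        specs = (MarkerSpec("z", "binary", ("0", "1"), "0"),)
        z = ["1"] + ["0"] * 39
        t = np.array([0] * 20 + [1] * 20)
        y = np.array([0, 1] * 20)
        ds = TrialDataset(t, y, pd.DataFrame({"z": z}), specs)
        res = build_rare_subgroup_model(specs)
        with pytest.raises(UndefinedEstimateError):
            population_impact(ds, res)


def build_rare_subgroup_model(specs):
    """A frozen model that is multimarker positive only when z = 1."""
    import pandas as pd

    from treatbenefit import TreatmentBenefitResults

    names = ["intercept", "treatment", "z", "treatment:z"]
    params = pd.Series([0.0, 1.0, 0.0, -3.0], index=names)
    return TreatmentBenefitResults(
        coefficient_names=names, params=params,
        bse=pd.Series(0.5, index=names), shrinkage_factor=1.0,
        is_shrunken=False, marker_specs=specs, threshold=0.0)


class TestCalibrationTable:
    def test_even_division(self, pessary_spec, reference_model):
        ds = generate_trial(pessary_spec, 100, seed=4)
        tab = calibration_table(ds, reference_model, n_groups=10)
        assert list(tab.frame["size"]) == [10] * 10
        assert tab.frame["size"].sum() == 100

    def test_remainder_goes_to_lowest_groups(self, pessary_spec,
                                             reference_model):
        ds = generate_trial(pessary_spec, 105, seed=4)
        tab = calibration_table(ds, reference_model, n_groups=10)
        assert list(tab.frame["size"]) == [11] * 5 + [10] * 5

    def test_groups_ordered_by_predicted_benefit(self, pessary_spec,
                                                 reference_model):
        ds = generate_trial(pessary_spec, 400, seed=4)
        tab = calibration_table(ds, reference_model)
        mp = tab.frame["mean_predicted_benefit"].to_numpy()
        assert np.all(np.diff(mp) >= -1e-12)

    def test_constant_benefit_still_well_formed(self, pessary_spec):
        ds = generate_trial(pessary_spec, 80, seed=4)
        tab = calibration_table(ds, null_model(), n_groups=4)
        assert tab.frame["mean_predicted_benefit"].nunique() == 1
        assert tab.frame["size"].sum() == 80

    def test_too_many_groups_rejected(self, pessary_spec,
                                      reference_model):
        ds = generate_trial(pessary_spec, 30, seed=4)
        with pytest.raises(ValueError):
            calibration_table(ds, reference_model, n_groups=20)

    @settings(derandomize=True, max_examples=25, deadline=None)
    @given(n=st.integers(40, 200), n_groups=st.integers(2, 12))
    def test_partition_property(self, pessary_spec, reference_model, n,
                                n_groups):
        """Groups partition the dataset with sizes differing by <= 1."""
        if n < 2 * n_groups:
            return
        ds = generate_trial(pessary_spec, n, seed=99)
        tab = calibration_table(ds, reference_model, n_groups=n_groups)
        sizes = tab.frame["size"]
        assert sizes.sum() == n
        assert sizes.max() - sizes.min() <= 1


class TestBootstrapPerformance:
    def test_same_seed_identical_cis(self, micro_trial, micro_fit):
        a = bootstrap_performance(micro_trial, micro_fit, n_boot=100,
                                  seed=11)
        b = bootstrap_performance(micro_trial, micro_fit, n_boot=100,
                                  seed=11)
        assert a.to_dict() == b.to_dict()

    def test_ci_contains_point_estimate(self, micro_trial, micro_fit):
        s = bootstrap_performance(micro_trial, micro_fit, n_boot=200,
                                  seed=12)
        assert (s.positivity_rate.ci_low <= 0.5
                <= s.positivity_rate.ci_high)
        assert (s.population_impact.ci_low
                <= s.population_impact.value
                <= s.population_impact.ci_high)

    def test_small_n_boot_rejected(self, micro_trial, micro_fit):
        with pytest.raises(ValueError):
            bootstrap_performance(micro_trial, micro_fit, n_boot=50,
                                  seed=1)

    def test_fragile_subgroup_raises_ci_error(self):
        # exactly one positive patient per arm: resampling loses one
        # of them far more often than the 20% failure budget allows
        specs = (MarkerSpec("z", "binary", ("0", "1"), "0"),)
        z = ["1", "1"] + ["0"] * 98
        t = np.array([0, 1] * 50)
        y = np.array(([1] * 10 + [0] * 40) * 2)
        ds = TrialDataset(t, y, pd.DataFrame({"z": z}), specs)
        res = build_rare_subgroup_model(specs)
        with pytest.raises(CIError):
            bootstrap_performance(ds, res, n_boot=100, seed=3,
                                  refit=False)


class TestExternalValidate:
    def test_self_validation_identity(self, micro_trial, micro_fit):
        summary, _ = external_validate(micro_fit, micro_trial,
                                       n_boot=None, n_groups=4)
        direct = population_impact(micro_trial, micro_fit)
        assert summary.positivity_rate.value == direct.positivity_rate.value
        assert (summary.population_impact.value
                == direct.population_impact.value)

    def test_exchangeable_validation_trial_agrees(self, pessary_spec):
        dev = generate_trial(pessary_spec, 4000, seed=21)
        fit = fit_interaction_model(dev)
        val = generate_trial(pessary_spec, 4000, seed=22)
        s_dev = population_impact(dev, fit)
        s_val, _ = external_validate(fit, val, n_boot=None)
        assert s_val.population_impact.value == pytest.approx(
            s_dev.population_impact.value, abs=0.05)

    def test_reversed_effects_detected_by_calibration(self, pessary_spec):
        """Transporting the model to a population whose treatment effects
        are reversed should show a negative benefit-calibration slope."""
        dev = generate_trial(pessary_spec, 6000, seed=31)
        fit = fit_interaction_model(dev)
        flipped = {k: (-v if k == "treatment" or k.startswith("treatment:")
                       else v)
                   for k, v in pessary_spec.true_coefficients.items()}
        spec_flip = SyntheticSpec(pessary_spec.marker_specs,
                                  pessary_spec.marker_prevalences,
                                  pessary_spec.allocation_ratio, flipped)
        val = generate_trial(spec_flip, 20_000, seed=32)
        _, table = external_validate(fit, val, n_boot=None)
        assert table.slope() < 0

    def test_marker_mismatch_lists_differences(self, micro_trial,
                                               reference_model):
        with pytest.raises(SchemaError, match="monochorionic"):
            external_validate(reference_model, micro_trial, n_boot=None)
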