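"""Analytic decision-tree expectations against the published base case."""

import copy

import pytest
from hypothesis import given, settings, strategies as st

from sepsis_cea import (
    TestCharacteristics,
    evaluate_arm,
    expected_los,
    in_hospital_mortality,
    incremental,
    leaf_probabilities,
    readmission_proportion,
    sepsis_survivor_1yr,
    worked_example_prediction_cost,
)


class TestLeafProbabilities:
    def test_base_case_products(self):
        leaves = leaf_probabilities(0.141, TestCharacteristics(0.80, 0.851))
        assert leaves.tp == pytest.approx(0.1128)
        assert leaves.fn == pytest.approx(0.0282)
        assert leaves.tn == pytest.approx(0.731009)
        assert leaves.fp == pytest.approx(0.127991)

    def test_perfect_test_has_no_errors(self):
        leaves = leaf_probabilities(0.141, TestCharacteristics(1.0, 1.0))
        assert leaves.fn == leaves.fp == 0.0

    def test_zero_incidence(self):
        leaves = leaf_probabilities(0.0, TestCharacteristics(0.8, 0.9))
        assert leaves.tp == leaves.fn == 0.0
        assert leaves.tn + leaves.fp == pytest.approx(1.0)

    @given(
        inc=st.floats(0, 1), sens=st.floats(0.01, 1), spec=st.floats(0.01, 1)
    )
    @settings(max_examples=200, deadline=None)
    def test_leaves_partition_the_cohort(self, inc, sens, spec):
        leaves = leaf_probabilities(inc, TestCharacteristics(sens, spec))
        assert leaves.total == pytest.approx(1.0, abs=1e-12)
        assert leaves.tp + leaves.fn == pytest.approx(inc, abs=1e-12)


class TestArmExpectations:
    def test_expected_icu_days(self, base_config):
        icu_a, _ = expected_los(base_config, "algorithm")
        icu_c, _ = expected_los(base_config, "comparator")
        assert round(icu_a, 2) == 1.62
        assert round(icu_c, 2) == 1.78
        assert icu_a == pytest.approx(1.6241, abs=5e-4)

    def test_expected_ward_days(self, base_config):
        _, ward_a = expected_los(base_config, "algorithm")
        _, ward_c = expected_los(base_config, "comparator")
        # weighted-sum oracle over the 4 leaves (shock mixing at -3/+3 h)
        assert ward_a == pytest.approx(6.4431, abs=0.01)
        assert round(ward_c, 2) == 6.66

    def test_in_hospital_mortality(self, base_config):
        assert in_hospital_mortality(base_config, "algorithm") == pytest.approx(
            0.02751, abs=5e-5
        )
        assert in_hospital_mortality(base_config, "comparator") == pytest.approx(
            0.03715, abs=5e-5
        )

    def test_mortality_zero_without_sepsis(self, config):
        config.cohort.incidence = 1e-12
        assert in_hospital_mortality(config, "algorithm") == pytest.approx(0, abs=1e-12)

    def test_readmission_proportion(self, base_config):
        assert round(100 * readmission_proportion(base_config, "algorithm"), 1) == 20.0
        assert round(100 * readmission_proportion(base_config, "comparator"), 1) == 19.8

    def test_readmission_zero_rate(self, config):
        config.postdischarge.readmission_rate_year1 = 0.0
        assert readmission_proportion(config, "algorithm") == 0.0

    def test_sepsis_survivor_1yr(self, base_config):
        assert sepsis_survivor_1yr(base_config, "algorithm") == pytest.approx(
            0.10678, abs=5e-5
        )
        assert sepsis_survivor_1yr(base_config, "comparator") == pytest.approx(
            0.09551, abs=5e-5
        )


class TestEvaluateArm:
    def test_total_cost_is_sum_of_components(self, base_config, life_table):
        arm = evaluate_arm(base_config, "algorithm", life_table)
        assert arm.cost_total == pytest.approx(
            arm.cost_prediction + arm.cost_icu + arm.cost_ward
            + arm.cost_readmission + arm.cost_longterm,
            abs=0.01,
        )

    def test_comparator_total_cost(self, base_config, life_table):
        arm = evaluate_arm(base_config, "comparator", life_table)
        assert arm.cost_total == pytest.approx(16_512, abs=5)
        assert arm.cost_prediction == 0.0

    def test_algorithm_longterm_cost(self, base_config, life_table):
        arm = evaluate_arm(base_config, "algorithm", life_table)
        assert arm.cost_longterm == pytest.approx(208, abs=1)

    def test_invalid_config_raises(self, config):
        config.cohort.incidence = 2.0
        with pytest.raises(ValueError, match="incidence"):
            evaluate_arm(config, "algorithm")

    def test_unknown_arm_rejected(self, base_config):
        with pytest.raises(ValueError, match="arm"):
            evaluate_arm(base_config, "placebo")


class TestIncremental:
    def test_per_patient_and_national_results(self, base_config, life_table):
        result = incremental(base_config, life_table)
        assert result.per_patient["cost_total"] == pytest.approx(-76, abs=1)
        assert result.lives_saved_national == pytest.approx(356, abs=1)
        assert result.icu_days_saved_national == pytest.approx(5860, rel=0.01)

    def test_national_is_exact_scaling(self, base_config, life_table):
        result = incremental(base_config, life_table)
        n = base_config.cohort.n_icu_admissions_no_sepsis
        for key, per_patient in result.per_patient.items():
            assert result.national[key] == per_patient * n

    def test_identical_arms_give_zero_increment(self, config, life_table):
        config.algorithm_test = copy.deepcopy(config.comparator_test)
        config.timing.t_tp = 0.0
        config.costs.prediction_cost_per_patient = 0.0
        result = incremental(config, life_table)
        for value in result.per_patient.values():
            assert value == pytest.approx(0.0, abs=1e-12)

    def test_base_case_is_dominant(self, base_config, life_table):
        result = incremental(base_config, life_table)
        assert result.icer.classification == "dominant"
        assert result.per_patient["qalys"] > 0

    def test_earlier_detection_never_hurts(self, config, life_table):
        """Moving detection earlier (more negative t_tp) cannot increase
        expected days, mortality, or sepsis-attributable cost."""
        prev = None
        for t_tp in (0.0, -1.0, -2.0, -3.0, -4.0):
            config.timing.t_tp = t_tp
            arm = evaluate_arm(config, "algorithm", life_table)
            if prev is not None:
                assert arm.expected_icu_days <= prev.expected_icu_days + 1e-12
                assert arm.expected_ward_days <= prev.expected_ward_days + 1e-12
                assert arm.in_hospital_mortality <= prev.in_hospital_mortality + 1e-12
                assert arm.cost_total <= prev.cost_total + 1e-9
            prev = arm

    def test_expectations_are_convex_combinations(self, base_config):
        """Expected ICU days lie between the smallest and largest leaf stay."""
        icu, ward = expected_los(base_config, "algorithm")
        los = base_config.los
        assert los.icu_true_negative <= icu <= los.icu_shock
        assert los.ward_noshock <= ward <= los.ward_shock


class TestWorkedExamplePredictionCost:
    def test_published_pricing_example(self, base_config):
        per_patient, _ = worked_example_prediction_cost(90.0, 1.62, 0.141)
        assert per_patient == pytest.approx(146, abs=1)
        icu_days, _ = expected_los(base_config, "algorithm")
        _, per_sepsis = worked_example_prediction_cost(90.0, icu_days, 0.141)
        assert per_sepsis == pytest.approx(1037, abs=3)

    def test_zero_price(self):
        assert worked_example_prediction_cost(0.0, 1.62, 0.141) == (0.0, 0.0)

    def test_zero_incidence_rejected(self):
        with pytest.raises(ValueError, match="incidence"):
            worked_example_prediction_cost(90.0, 1.62, 0.0)
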