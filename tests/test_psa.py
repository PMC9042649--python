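"""Distribution builders and the probabilistic sensitivity analysis."""

import math

import numpy as np
import pytest

from sepsis_cea import (
    beta_from_moments,
    conditioned_psa,
    gamma_from_moments,
    incremental,
    lognormal_from_moments,
    run_psa,
    threshold_fraction,
)
from sepsis_cea.parameters import DistributionSpec
from sepsis_cea.psa import sample_parameter


class TestMomentBuilders:
    @pytest.mark.parametrize(
        "mean, se", [(0.141, 0.0038), (0.566, 0.0091), (0.8, 0.0183)]
    )
    def test_beta_round_trip(self, mean, se):
        a, b = beta_from_moments(mean, se)
        assert a / (a + b) == pytest.approx(mean, abs=1e-9)
        var = a * b / ((a + b) ** 2 * (a + b + 1))
        assert math.sqrt(var) == pytest.approx(se, abs=1e-9)

    def test_beta_published_row(self):
        a, b = beta_from_moments(0.141, 0.0038)
        assert a == pytest.approx(1182.5, rel=0.01)
        assert b == pytest.approx(7204.2, rel=0.01)

    def test_beta_symmetry_at_half(self):
        a, b = beta_from_moments(0.5, 0.001)
        assert a == pytest.approx(b)

    def test_beta_infeasible_moments(self):
        with pytest.raises(ValueError, match="moment condition"):
            beta_from_moments(0.5, 0.6)

    @pytest.mark.parametrize("mean, se", [(7.4, 0.1989), (17.0, 0.4570)])
    def test_gamma_round_trip(self, mean, se):
        shape, scale = gamma_from_moments(mean, se)
        assert shape * scale == pytest.approx(mean, abs=1e-9)
        assert math.sqrt(shape) * scale == pytest.approx(se, abs=1e-9)

    def test_gamma_published_row(self):
        shape, scale = gamma_from_moments(7.4, 0.1989)
        assert shape == pytest.approx(1384.2, rel=0.01)
        assert scale == pytest.approx(0.005346, rel=0.01)

    def test_gamma_exponential_special_case(self):
        assert gamma_from_moments(1.0, 1.0) == (pytest.approx(1.0), pytest.approx(1.0))

    def test_gamma_rejects_zero_se(self):
        with pytest.raises(ValueError):
            gamma_from_moments(2.0, 0.0)

    def test_lognormal_round_trip(self):
        mu, sigma = lognormal_from_moments(1.0, 0.255)
        assert math.exp(mu + sigma**2 / 2) == pytest.approx(1.0, abs=1e-9)
        var = (math.exp(sigma**2) - 1) * math.exp(2 * mu + sigma**2)
        assert math.sqrt(var) == pytest.approx(0.255, abs=1e-9)

    def test_lognormal_small_se_limits(self):
        mu, sigma = lognormal_from_moments(1.0, 1e-9)
        assert mu == pytest.approx(0.0, abs=1e-12)
        mu_e, _ = lognormal_from_moments(math.e, 1e-9)
        assert mu_e == pytest.approx(1.0, abs=1e-12)

    @pytest.mark.parametrize(
        "spec",
        [
            DistributionSpec("p", "beta", 0.141, 0.0038),
            DistributionSpec("d", "gamma", 7.4, 0.1989),
            DistributionSpec("rr", "lognormal", 1.0, 0.255),
            DistributionSpec("t", "normal", -3.0, 0.5),
        ],
        ids=lambda s: s.family,
    )
    def test_empirical_moment_recovery(self, spec):
        """1e6 seeded draws recover the published mean and SE within 3 MC
        standard errors."""
        n = 1_000_000
        draws = sample_parameter(spec, np.random.default_rng(123), n)
        se_mean = draws.std(ddof=1) / math.sqrt(n)
        assert abs(draws.mean() - spec.mean) < 3 * se_mean
        # SE of the sample SD ~ sd / sqrt(2(n-1)) (normal approximation)
        se_sd = draws.std(ddof=1) / math.sqrt(2 * (n - 1))
        assert abs(draws.std(ddof=1) - spec.se) < 5 * se_sd

    def test_zero_se_is_degenerate(self):
        spec = DistributionSpec("u", "normal", -0.164, 0.0)
        draws = sample_parameter(spec, np.random.default_rng(0), 100)
        assert (draws == -0.164).all()


class TestRunPsa:
    def test_bit_reproducible_for_fixed_seed(self, base_config, life_table):
        r1 = run_psa(base_config, n_draws=50, seed=42, life_table=life_table)
        r2 = run_psa(base_config, n_draws=50, seed=42, life_table=life_table)
        assert np.array_equal(r1.delta_cost, r2.delta_cost)
        assert np.array_equal(r1.delta_qaly, r2.delta_qaly)
        assert r1.draws.equals(r2.draws)

    def test_all_se_zero_collapses_to_deterministic(self, config, life_table):
        for spec in config.psa_specs:
            spec.se = 0.0
        result = run_psa(config, n_draws=20, seed=1, life_table=life_table)
        base = incremental(config, life_table=life_table)
        assert result.delta_cost == pytest.approx(
            [base.per_patient["cost_total"]] * 20, abs=1e-9
        )
        assert result.delta_qaly == pytest.approx(
            [base.per_patient["qalys"]] * 20, abs=1e-12
        )

    def test_majority_of_draws_are_cost_saving(self, base_config, life_table):
        result = run_psa(base_config, n_draws=300, seed=42, life_table=life_table)
        assert np.mean(result.delta_cost < 0) > 0.5

    def test_summary_consistent_with_draws(self, base_config, life_table):
        result = run_psa(base_config, n_draws=200, seed=7, life_table=life_table)
        s = result.summary
        assert s["min"] <= s["q1"] <= s["median"] <= s["q3"] <= s["max"]
        assert s["median"] == pytest.approx(float(np.median(result.delta_cost)))
        assert set(result.fraction_below_threshold) == {20_000.0, 50_000.0}


class TestConditionedPsa:
    def test_conditioned_parameter_is_constant(self, base_config, life_table):
        result = conditioned_psa(
            base_config, "incidence", n_draws=50, seed=42, life_table=life_table
        )
        assert (result.draws["incidence"] == 0.141).all()

    def test_unknown_parameter_lists_valid_names(self, base_config):
        with pytest.raises(KeyError, match="incidence"):
            conditioned_psa(base_config, "nonexistent", n_draws=5, seed=0)

    def test_conditioning_on_zero_se_parameter_changes_nothing(
        self, base_config, life_table
    ):
        plain = run_psa(base_config, n_draws=40, seed=9, life_table=life_table)
        cond = conditioned_psa(
            base_config, "utility_decrement_years_11_plus",
            n_draws=40, seed=9, life_table=life_table,
        )
        assert np.array_equal(plain.delta_cost, cond.delta_cost)

    def test_conditioning_on_influential_parameter_reduces_variance(
        self, base_config, life_table
    ):
        """Holding the most influential parameter (incidence) at its mean
        shrinks the incremental-cost variance, other streams unchanged."""
        plain = run_psa(base_config, n_draws=300, seed=42, life_table=life_table)
        cond = conditioned_psa(
            base_config, "incidence", n_draws=300, seed=42, life_table=life_table
        )
        assert cond.delta_cost.var() < plain.delta_cost.var()


class TestThresholdFraction:
    def _result(self, dc, dq):
        from sepsis_cea.psa import PsaResult
        import pandas as pd

        return PsaResult(
            n_draws=len(dc), seed=0, conditioned_on=None,
            delta_cost=np.asarray(dc, dtype=float),
            delta_qaly=np.asarray(dq, dtype=float),
            draws=pd.DataFrame(), summary={}, fraction_dominant=0.0,
            fraction_below_threshold={},
        )

    def test_all_dominant(self):
        r = self._result([-10, -20], [0.1, 0.2])
        assert threshold_fraction(r, 20_000) == 1.0

    def test_all_dominated(self):
        r = self._result([10, 20], [-0.1, -0.2])
        assert threshold_fraction(r, 50_000) == 0.0

    def test_monotone_in_willingness_to_pay(self, base_config, life_table):
        result = run_psa(base_config, n_draws=200, seed=42, life_table=life_table)
        assert threshold_fraction(result, 50_000) >= threshold_fraction(result, 20_000)
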