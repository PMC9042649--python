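"""Probabilistic sensitivity analysis with method-of-moments distributions.

Every uncertain parameter is assigned a distribution family (beta for
probabilities, gamma for lengths of stay, log-normal for relative risks,
normal for timing and utility decrements) whose parameters are recovered
from the published mean and standard error by the method of moments.  Each
parameter draws from its own random stream derived from the master seed, so
conditioning one parameter at its mean (the "conditioned PSA") leaves every
other parameter's draws unchanged.

Each draw overlays the sampled values on the base configuration, re-runs
the full decision-tree and long-term model, and records the incremental
cost and QALYs; the result summarises the cloud (quartiles, whiskers,
dominance fraction, and fractions below the willingness-to-pay thresholds).
"""

from __future__ import annotations

import copy
import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .decision_tree import incremental
from .longterm import LifeTable, icer
from .parameters import DistributionSpec, ModelConfig

logger = logging.getLogger(__name__)

__all__ = [
    "PsaResult",
    "beta_from_moments",
    "gamma_from_moments",
    "lognormal_from_moments",
    "sample_parameter",
    "run_psa",
    "conditioned_psa",
    "threshold_fraction",
]


def beta_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Beta(alpha, beta) with the given mean and standard error."""
    if not 0 < mean < 1:
        raise ValueError(f"beta mean {mean} must lie in (0, 1)")
    if se <= 0:
        raise ValueError("beta se must be positive")
    if se * se >= mean * (1 - mean):
        raise ValueError(
            f"beta moment condition violated: se^2 = {se * se:.4g} >= "
            f"mean(1-mean) = {mean * (1 - mean):.4g}"
        )
    nu = mean * (1 - mean) / (se * se) - 1.0
    return mean * nu, (1 - mean) * nu


def gamma_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Gamma(shape, scale) with the given mean and standard error."""
    if mean <= 0 or se <= 0:
        raise ValueError("gamma mean and se must be positive")
    return (mean / se) ** 2, se * se / mean


def lognormal_from_moments(mean: float, se: float) -> tuple[float, float]:
    """Log-normal(mu, sigma) with the given arithmetic mean and SE."""
    if mean <= 0:
        raise ValueError("lognormal mean must be positive")
    if se <= 0:
        raise ValueError("lognormal se must be positive")
    sigma2 = math.log(1.0 + (se * se) / (mean * mean))
    mu = math.log(mean) - sigma2 / 2.0
    return mu, math.sqrt(sigma2)


def sample_parameter(
    spec: DistributionSpec, rng: np.random.Generator, size: int
) -> np.ndarray:
    """Draw ``size`` values from the spec's method-of-moments distribution.

    A standard error of 0 denotes a degenerate parameter fixed at its mean.
    """
    if spec.se == 0:
        return np.full(size, spec.mean)
    if spec.family == "beta":
        a, b = beta_from_moments(spec.mean, spec.se)
        return rng.beta(a, b, size)
    if spec.family == "gamma":
        shape, scale = gamma_from_moments(spec.mean, spec.se)
        return rng.gamma(shape, scale, size)
    if spec.family == "lognormal":
        mu, sigma = lognormal_from_moments(spec.mean, spec.se)
        return rng.lognormal(mu, sigma, size)
    if spec.family == "normal":
        return rng.normal(spec.mean, spec.se, size)
    raise ValueError(f"unknown distribution family {spec.family!r}")


# ---------------------------------------------------------------------------
# Overlay: map sampled parameter names onto the config
# ---------------------------------------------------------------------------

def _set_hr_band(config: ModelConfig, band: str, years: str, value: float) -> None:
    """Apply a long-term hazard-ratio draw if the cohort age selects its band."""
    age = config.cohort.mean_age
    selected = (
        (band == "under60" and age < 60)
        or (band == "60to70" and 60 <= age <= 70)
        or (band == "over70" and age > 70)
    )
    if selected:
        setattr(config.longterm, f"rr_years_{years}", value)


def _apply_sample(config: ModelConfig, name: str, value: float) -> None:
    lt = config.longterm
    simple = {
        "incidence": lambda v: setattr(config.cohort, "incidence", v),
        "sensitivity_algorithm": lambda v: setattr(config.algorithm_test, "sensitivity", v),
        "specificity_algorithm": lambda v: setattr(config.algorithm_test, "specificity", v),
        "sensitivity_comparator": lambda v: setattr(config.comparator_test, "sensitivity", v),
        "specificity_comparator": lambda v: setattr(config.comparator_test, "specificity", v),
        "hours_to_treatment_tp": lambda v: setattr(config.timing, "t_tp", v),
        "hours_to_treatment_fn": lambda v: setattr(config.timing, "t_fn", v),
        "hours_to_antibiotic": lambda v: setattr(
            config.timing, "t_antibiotic_from_detection", v
        ),
        "shock_probability_early": lambda v: setattr(config.shock_risk, "p_early", v),
        "shock_probability_soc": lambda v: setattr(config.shock_risk, "p_ref", v),
        "rr_mortality_shock": lambda v: setattr(
            config.mortality, "rr_shock_multiplier", v
        ),
        "rr_mortality_nonshock": lambda v: setattr(
            config.mortality, "rr_noshock_multiplier", v
        ),
        "icu_days_shock": lambda v: setattr(config.los, "icu_shock", v),
        "icu_days_noshock": lambda v: setattr(config.los, "icu_noshock", v),
        "icu_days_true_negative": lambda v: setattr(config.los, "icu_true_negative", v),
        "icu_days_false_positive": lambda v: setattr(config.los, "icu_false_positive", v),
        "ward_days_shock": lambda v: setattr(config.los, "ward_shock", v),
        "ward_days_noshock": lambda v: setattr(config.los, "ward_noshock", v),
        "ward_days_true_negative": lambda v: setattr(config.los, "ward_true_negative", v),
        "ward_days_false_positive": lambda v: setattr(config.los, "ward_false_positive", v),
        "postdischarge_mortality_shock": lambda v: setattr(
            config.postdischarge, "postdischarge_mortality_year1_shock", v
        ),
        "readmission_rate": lambda v: setattr(
            config.postdischarge, "readmission_rate_year1", v
        ),
        "utility_decrement_years_1_5": lambda v: setattr(
            lt, "utility_decrement_years_1_5", v
        ),
        "utility_decrement_years_6_10": lambda v: setattr(
            lt, "utility_decrement_years_6_10", v
        ),
        "utility_decrement_years_11_plus": lambda v: setattr(
            lt, "utility_decrement_years_11_plus", v
        ),
    }
    if name in simple:
        simple[name](value)
        return
    if name.startswith("hr_years_"):
        # hr_years_<years>_<band>, e.g. hr_years_1_5_60to70
        stem = name[len("hr_years_"):]
        years, band = stem.rsplit("_", 1)
        _set_hr_band(config, band, years, value)
        return
    if name.startswith("freq_"):
        key = name[len("freq_"):]
        if key in lt.consequence_frequencies:
            lt.consequence_frequencies[key] = value
            return
    raise KeyError(f"no overlay mapping for sampled parameter {name!r}")


def _repair_draw(config: ModelConfig) -> bool:
    """Clamp a sampled config back into its support; True if anything moved."""
    clamped = False
    sr = config.shock_risk
    if sr.p_early > sr.p_ref:
        sr.p_early = sr.p_ref
        clamped = True
    if config.timing.t_tp > config.timing.t_fn:
        config.timing.t_tp = config.timing.t_fn
        clamped = True
    lt = config.longterm
    for name in ("rr_years_1_5", "rr_years_6_10", "rr_years_11_plus"):
        if getattr(lt, name) < 1.0:
            setattr(lt, name, 1.0)
            clamped = True
    return clamped


@dataclass
class PsaResult:
    """Sampled incremental cost/QALY cloud and its summary statistics."""

    n_draws: int
    seed: int
    conditioned_on: str | None
    delta_cost: np.ndarray
    delta_qaly: np.ndarray
    draws: pd.DataFrame
    summary: dict[str, float]
    fraction_dominant: float
    fraction_below_threshold: dict[float, float]
    n_clamped: int = 0

    def to_csv(self, path) -> None:
        self.draws.to_csv(path, index=False)


def _box_summary(values: np.ndarray) -> dict[str, float]:
    q1, med, q3 = np.percentile(values, [25, 50, 75])
    iqr = q3 - q1
    lo = values[values >= q1 - 1.5 * iqr].min()
    hi = values[values <= q3 + 1.5 * iqr].max()
    return {
        "mean": float(values.mean()),
        "min": float(values.min()),
        "whisker_low": float(lo),
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "whisker_high": float(hi),
        "max": float(values.max()),
    }


def threshold_fraction(result: "PsaResult", wtp: float) -> float:
    """Fraction of draws cost-effective at the willingness-to-pay threshold.

    A draw counts if it is dominant (cheaper, more effective) or if it buys
    QALYs at a ratio below ``wtp``; dominated draws never count.
    """
    dc, dq = result.delta_cost, result.delta_qaly
    dominant = (dc <= 0) & (dq > 0)
    buys = (dq > 0) & (dc > 0) & (dc / dq < wtp)
    return float(np.mean(dominant | buys))


def run_psa(
    config: ModelConfig,
    n_draws: int = 1000,
    seed: int = 0,
    life_table: LifeTable | None = None,
    _condition_on: str | None = None,
) -> PsaResult:
    """Monte-Carlo propagation of parameter uncertainty through the model.

    Deterministic for a fixed (seed, n_draws): parameter i draws from
    ``default_rng([seed, i])`` in the distribution-table row order.
    Sampled configs falling outside their support (e.g. an early-detection
    shock probability drawn above the current-practice one) are clamped
    back and counted; more than 1% clamped draws logs a warning.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    specs = config.psa_specs
    if not specs:
        raise ValueError("config has no psa_specs to sample")
    names = [s.parameter_name for s in specs]
    if _condition_on is not None and _condition_on not in names:
        raise KeyError(
            f"unknown parameter {_condition_on!r}; valid names: {', '.join(names)}"
        )

    samples = np.empty((n_draws, len(specs)))
    for i, spec in enumerate(specs):
        rng = np.random.default_rng([seed, i])
        if spec.parameter_name == _condition_on:
            samples[:, i] = spec.mean
        else:
            samples[:, i] = sample_parameter(spec, rng, n_draws)

    delta_cost = np.empty(n_draws)
    delta_qaly = np.empty(n_draws)
    n_clamped = 0
    for d in range(n_draws):
        draw_cfg = copy.deepcopy(config)
        for i, spec in enumerate(specs):
            _apply_sample(draw_cfg, spec.parameter_name, float(samples[d, i]))
        if _repair_draw(draw_cfg):
            n_clamped += 1
        inc = incremental(draw_cfg, life_table=life_table)
        delta_cost[d] = inc.per_patient["cost_total"]
        delta_qaly[d] = inc.per_patient["qalys"]
    if n_clamped > 0.01 * n_draws:
        logger.warning(
            "%d of %d PSA draws required clamping back into support",
            n_clamped, n_draws,
        )

    classes = [icer(c, q).classification for c, q in zip(delta_cost, delta_qaly)]
    draws = pd.DataFrame(samples, columns=names)
    draws["delta_cost"] = delta_cost
    draws["delta_qaly"] = delta_qaly
    draws["icer_class"] = classes
    result = PsaResult(
        n_draws=n_draws,
        seed=seed,
        conditioned_on=_condition_on,
        delta_cost=delta_cost,
        delta_qaly=delta_qaly,
        draws=draws,
        summary=_box_summary(delta_cost),
        fraction_dominant=float(
            np.mean((delta_cost <= 0) & (delta_qaly > 0))
        ),
        fraction_below_threshold={},
        n_clamped=n_clamped,
    )
    return _finalise_thresholds(result, config.wtp_thresholds)


def _finalise_thresholds(result: PsaResult, thresholds) -> PsaResult:
    result.fraction_below_threshold = {
        float(w): threshold_fraction(result, w) for w in thresholds
    }
    return result


def conditioned_psa(
    config: ModelConfig,
    parameter_name: str,
    n_draws: int = 1000,
    seed: int = 0,
    life_table: LifeTable | None = None,
) -> PsaResult:
    """PSA with one parameter held constant at its mean.

    All other parameters vary exactly as in ``run_psa`` with the same seed,
    isolating the named parameter's contribution to overall uncertainty.
    """
    result = run_psa(
        config, n_draws=n_draws, seed=seed, life_table=life_table,
        _condition_on=parameter_name,
    )
    return _finalise_thresholds(result, config.wtp_thresholds)
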