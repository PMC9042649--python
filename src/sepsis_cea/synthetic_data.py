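"""Synthetic inputs: life tables, grouped mortality data, and a microsimulation.

Everything the pipeline consumes can be generated here without external
downloads:

* a Gompertz general-population life table (annual death probability rising
  exponentially with age) standing in for the national statistics table,
  explicitly synthetic and non-official;
* grouped "delay-to-treatment vs cumulative mortality" datasets drawn from a
  known generating curve, for exercising the two-step curve-estimation
  procedure with a known truth;
* an individual-patient Monte-Carlo simulation of the decision tree, used
  as an independent oracle for the analytic cohort expectations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .longterm import LifeTable, discounted_qalys, project_survival
from .parameters import ModelConfig, validate_config
from .risk_models import (
    GroupedMortalityData,
    MortalityCurves,
    mortality_nonshock,
    mortality_shock,
    shock_probability,
)

__all__ = [
    "GompertzLifeTableSpec",
    "CohortSimulationResult",
    "generate_life_table",
    "default_life_table",
    "generate_grouped_mortality",
    "simulate_cohort",
]


@dataclass
class GompertzLifeTableSpec:
    """Gompertz mortality law q(x) = min(1, A * exp(B * x)).

    Defaults give a plausible high-income-country table (remaining life
    expectancy at 60 of roughly two decades); purely synthetic, not an
    official national life table.
    """

    A: float = 5e-5
    B: float = 0.095
    max_age: int = 105


def generate_life_table(spec: GompertzLifeTableSpec | None = None) -> LifeTable:
    """Annual death probabilities on ages 0..max_age, terminal q = 1."""
    if spec is None:
        spec = GompertzLifeTableSpec()
    if spec.A <= 0 or spec.B <= 0 or spec.max_age <= 0:
        raise ValueError("Gompertz parameters must be positive")
    ages = list(range(spec.max_age + 1))
    q = [min(1.0, spec.A * math.exp(spec.B * x)) for x in ages]
    q[-1] = 1.0
    return LifeTable(ages=ages, q=q)


_DEFAULT_TABLE: LifeTable | None = None


def default_life_table() -> LifeTable:
    """The cached default synthetic life table."""
    global _DEFAULT_TABLE
    if _DEFAULT_TABLE is None:
        _DEFAULT_TABLE = generate_life_table()
    return _DEFAULT_TABLE


def generate_grouped_mortality(
    curve: MortalityCurves,
    intervals: list[tuple[float, float]],
    n_per_interval: int,
    noise_seed: int,
    component: str = "shock",
) -> GroupedMortalityData:
    """Draw binomial death counts from a known mortality curve.

    Each delay interval's death probability is the curve evaluated at the
    interval midpoint (``component`` selects the shock or no-shock curve);
    counts are binomial draws, deterministic per seed.
    """
    if n_per_interval <= 0:
        raise ValueError("n_per_interval must be positive")
    if component not in ("shock", "nonshock"):
        raise ValueError(f"component must be 'shock' or 'nonshock', got {component!r}")
    rng = np.random.default_rng(noise_seed)
    rows = []
    grid = []
    for (s, e) in intervals:
        mid = 0.5 * (s + e)
        p = (
            mortality_shock(curve, mid)
            if component == "shock"
            else mortality_nonshock(curve, mid)
        )
        deaths = int(rng.binomial(n_per_interval, p))
        rows.append((float(s), float(e), int(n_per_interval), deaths))
        grid.append(mid)
    return GroupedMortalityData(intervals=rows, grid=grid)


@dataclass
class CohortSimulationResult:
    """Empirical decision-tree means from an individual-patient simulation."""

    arm: str
    n: int
    seed: int
    means: dict[str, float]
    se: dict[str, float]
    records: pd.DataFrame | None = None

    def to_csv(self, path) -> None:
        if self.records is None:
            raise ValueError("simulation was run without per-patient records")
        self.records.to_csv(path, index=False)


def simulate_cohort(
    config: ModelConfig,
    arm: str,
    n: int,
    seed: int,
    stochastic_los: bool = False,
    keep_records: bool = False,
) -> CohortSimulationResult:
    """Monte-Carlo realisation of the decision tree for ``n`` patients.

    Each patient is routed sepsis -> TP/FN (or no-sepsis -> TN/FP) by
    Bernoulli draws; septic shock and in-hospital death follow the risk
    functions at the leaf's treatment time; stays, costs, and conditional
    QALY expectations are assigned per leaf and severity.  With
    ``stochastic_los`` the stays are drawn from gamma distributions matched
    to the published means and standard errors instead of fixed at the
    means.  Empirical means converge to the analytic arm expectations.
    """
    from .decision_tree import arm_times, _arm_test  # local to avoid cycle

    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    if n < 1:
        raise ValueError("n must be >= 1")
    rng = np.random.default_rng(seed)
    inc = config.cohort.incidence
    test = _arm_test(config, arm)
    t_tp, t_fn = arm_times(config, arm)
    los, costs = config.los, config.costs

    sepsis = rng.random(n) < inc
    positive = np.where(
        sepsis, rng.random(n) < test.sensitivity, rng.random(n) >= test.specificity
    )
    # leaf codes: 0=TP 1=FN 2=TN 3=FP
    leaf = np.where(
        sepsis, np.where(positive, 0, 1), np.where(positive, 3, 2)
    ).astype(np.int8)

    p_shock_tp = shock_probability(config.shock_risk, t_tp)
    p_shock_fn = shock_probability(config.shock_risk, t_fn)
    p_shock = np.where(leaf == 0, p_shock_tp, p_shock_fn)
    shock = sepsis & (rng.random(n) < p_shock)

    m_sh = np.where(
        leaf == 0,
        mortality_shock(config.mortality, t_tp),
        mortality_shock(config.mortality, t_fn),
    )
    m_ns = np.where(
        leaf == 0,
        mortality_nonshock(config.mortality, t_tp),
        mortality_nonshock(config.mortality, t_fn),
    )
    p_death = np.where(shock, m_sh, m_ns)
    death = sepsis & (rng.random(n) < p_death)

    def _gamma(mean, sd, size):
        shape = (mean / sd) ** 2
        scale = sd * sd / mean
        return rng.gamma(shape, scale, size)

    if stochastic_los:
        icu_by_leaf = {
            2: _gamma(los.icu_true_negative, 0.0264, n),
            3: _gamma(los.icu_false_positive, 0.0264, n),
        }
        icu_days = np.where(
            sepsis,
            np.where(shock, _gamma(los.icu_shock, 0.1989, n),
                     _gamma(los.icu_noshock, 0.1650, n)),
            np.where(leaf == 2, icu_by_leaf[2], icu_by_leaf[3]),
        )
        ward_days = np.where(
            sepsis,
            np.where(shock, _gamma(los.ward_shock, 0.4570, n),
                     _gamma(los.ward_noshock, 0.4703, n)),
            np.where(leaf == 2, _gamma(los.ward_true_negative, 0.1505, n),
                     _gamma(los.ward_false_positive, 0.1505, n)),
        )
    else:
        icu_days = np.select(
            [sepsis & shock, sepsis & ~shock, leaf == 2, leaf == 3],
            [los.icu_shock, los.icu_noshock, los.icu_true_negative,
             los.icu_false_positive],
        )
        ward_days = np.select(
            [sepsis & shock, sepsis & ~shock, leaf == 2, leaf == 3],
            [los.ward_shock, los.ward_noshock, los.ward_true_negative,
             los.ward_false_positive],
        )

    survivors = ~death
    rate = config.postdischarge.readmission_rate_year1
    if config.readmission_population == "sepsis_survivors":
        eligible = survivors & sepsis
    else:
        eligible = survivors
    readmitted = eligible & (rng.random(n) < rate)

    fym = config.postdischarge.postdischarge_mortality_year1_shock
    alive_1yr = sepsis & survivors & np.where(
        shock, rng.random(n) >= fym, True
    )

    # conditional QALY expectations per pathway status
    age = int(round(config.cohort.mean_age))
    life_table = default_life_table()
    proj_sepsis = project_survival(life_table, age, config.longterm, apply_rr=True)
    proj_gen = project_survival(life_table, age, config.longterm, apply_rr=False)
    q_shock = discounted_qalys(proj_sepsis, first_year_mortality=fym)
    q_noshock = discounted_qalys(proj_sepsis, first_year_mortality=0.0)
    q_gen = discounted_qalys(proj_gen)
    qalys = np.where(
        sepsis,
        np.where(death, 0.0, np.where(shock, q_shock, q_noshock)),
        q_gen,
    )

    horizon = config.longterm.time_horizon_years
    include_lt = config.longterm.include_longterm_consequences and (
        horizon is None or horizon > 1
    )
    cost_prediction = np.full(
        n, costs.prediction_cost_per_patient if arm == "algorithm" else 0.0
    )
    cost_icu = icu_days * costs.icu_day
    cost_ward = ward_days * costs.ward_day
    cost_readmission = readmitted * costs.readmission_event
    cost_longterm = (
        alive_1yr * costs.longterm_cost_per_survivor if include_lt else np.zeros(n)
    )
    cost_total = (
        cost_prediction + cost_icu + cost_ward + cost_readmission + cost_longterm
    )

    columns = {
        "expected_icu_days": icu_days.astype(float),
        "expected_ward_days": ward_days.astype(float),
        "in_hospital_mortality": death.astype(float),
        "readmission_proportion": readmitted.astype(float),
        "sepsis_survivor_1yr": alive_1yr.astype(float),
        "cost_prediction": cost_prediction.astype(float),
        "cost_icu": cost_icu.astype(float),
        "cost_ward": cost_ward.astype(float),
        "cost_readmission": cost_readmission.astype(float),
        "cost_longterm": np.asarray(cost_longterm, dtype=float),
        "cost_total": cost_total.astype(float),
        "qalys": qalys.astype(float),
    }
    leaf_fracs = {
        "leaf_tp": (leaf == 0).astype(float),
        "leaf_fn": (leaf == 1).astype(float),
        "leaf_tn": (leaf == 2).astype(float),
        "leaf_fp": (leaf == 3).astype(float),
    }
    all_cols = {**leaf_fracs, **columns}
    means = {k: float(v.mean()) for k, v in all_cols.items()}
    se = {k: float(v.std(ddof=1) / math.sqrt(n)) if n > 1 else float("inf")
          for k, v in all_cols.items()}

    records = None
    if keep_records:
        records = pd.DataFrame(
            {
                "leaf": np.array(["TP", "FN", "TN", "FP"])[leaf],
                "shock": shock,
                "death": death,
                "icu_days": icu_days,
                "ward_days": ward_days,
                "readmitted": readmitted,
                "alive_1yr": alive_1yr,
                "cost_total": cost_total,
                "qalys": qalys,
            }
        )
    return CohortSimulationResult(
        arm=arm, n=n, seed=seed, means=means, se=se, records=records
    )
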