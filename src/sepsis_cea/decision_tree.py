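"""Analytic cohort expectations for the sepsis-detection decision tree.

Patients admitted to the ICU without sepsis either develop sepsis
(incidence) or not; the screening method's sensitivity and specificity then
split them into true positives / false negatives and true negatives / false
positives.  True positives in the algorithm arm are treated earlier
(t = -3 h in the base case, relative to current-practice diagnosis at
t = 0); false negatives in both arms are treated +3 h late.  Treatment
timing drives septic-shock prevalence and in-hospital mortality through the
risk functions; each leaf carries its own ICU and ward lengths of stay.

``evaluate_arm`` assembles per-patient expectations (days, deaths,
readmissions, cost components, QALYs) for one arm; ``incremental`` takes
algorithm-minus-comparator differences and scales them to the national
annual cohort of ICU admissions without sepsis.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .longterm import (
    IcerResult,
    LifeTable,
    discounted_qalys,
    icer,
    longterm_consequence_cost,
    project_survival,
)
from .parameters import ModelConfig, TestCharacteristics, validate_config
from .risk_models import mortality_nonshock, mortality_shock, shock_probability

__all__ = [
    "LeafProbabilities",
    "ArmOutcome",
    "IncrementalResult",
    "leaf_probabilities",
    "arm_times",
    "expected_los",
    "in_hospital_mortality",
    "readmission_proportion",
    "sepsis_survivor_1yr",
    "evaluate_arm",
    "incremental",
    "worked_example_prediction_cost",
]

ARMS = ("algorithm", "comparator")


@dataclass
class LeafProbabilities:
    tp: float
    fn: float
    tn: float
    fp: float

    @property
    def total(self) -> float:
        return self.tp + self.fn + self.tn + self.fp


@dataclass
class ArmOutcome:
    """Per-patient expected values for one arm of the decision tree."""

    arm: str
    leaves: LeafProbabilities
    shock_probability_tp: float
    shock_probability_fn: float
    expected_icu_days: float
    expected_ward_days: float
    in_hospital_mortality: float
    readmission_proportion: float
    sepsis_survivor_1yr: float
    cost_prediction: float
    cost_icu: float
    cost_ward: float
    cost_readmission: float
    cost_longterm: float
    cost_total: float
    qalys: float


@dataclass
class IncrementalResult:
    """Algorithm-minus-comparator differences, per patient and national."""

    per_patient: dict[str, float]
    national: dict[str, float]
    lives_saved_national: float
    icu_days_saved_national: float
    ward_days_saved_national: float
    icer: IcerResult
    algorithm: ArmOutcome = None
    comparator: ArmOutcome = None


def leaf_probabilities(
    incidence: float, test: TestCharacteristics
) -> LeafProbabilities:
    """Split the cohort by sepsis incidence and test characteristics."""
    return LeafProbabilities(
        tp=incidence * test.sensitivity,
        fn=incidence * (1.0 - test.sensitivity),
        tn=(1.0 - incidence) * test.specificity,
        fp=(1.0 - incidence) * (1.0 - test.specificity),
    )


def _check_arm(arm: str) -> None:
    if arm not in ARMS:
        raise ValueError(f"arm must be one of {ARMS}, got {arm!r}")


def arm_times(config: ModelConfig, arm: str) -> tuple[float, float]:
    """Total hours to treatment for (true positives, false negatives).

    The comparator's true positives are treated at current-practice
    diagnosis (t = 0); both arms share the false-negative delay.  The
    antibiotic offset from detection shifts every pathway equally.
    """
    _check_arm(arm)
    ab = config.timing.t_antibiotic_from_detection
    t_tp = config.timing.t_tp if arm == "algorithm" else 0.0
    return t_tp + ab, config.timing.t_fn + ab


def _arm_test(config: ModelConfig, arm: str) -> TestCharacteristics:
    return config.algorithm_test if arm == "algorithm" else config.comparator_test


def expected_los(config: ModelConfig, arm: str) -> tuple[float, float]:
    """Probability-weighted expected (ICU days, ward days) per patient.

    Sepsis leaves mix shock and no-shock stays using the shock probability
    at the leaf's treatment time; TN/FP use their fixed stays.
    """
    _check_arm(arm)
    leaves = leaf_probabilities(config.cohort.incidence, _arm_test(config, arm))
    t_tp, t_fn = arm_times(config, arm)
    los = config.los
    icu = ward = 0.0
    for leaf_p, t in ((leaves.tp, t_tp), (leaves.fn, t_fn)):
        p_shock = shock_probability(config.shock_risk, t)
        icu += leaf_p * (p_shock * los.icu_shock + (1 - p_shock) * los.icu_noshock)
        ward += leaf_p * (p_shock * los.ward_shock + (1 - p_shock) * los.ward_noshock)
    icu += leaves.tn * los.icu_true_negative + leaves.fp * los.icu_false_positive
    ward += leaves.tn * los.ward_true_negative + leaves.fp * los.ward_false_positive
    return icu, ward


def in_hospital_mortality(config: ModelConfig, arm: str) -> float:
    """Expected in-hospital mortality per ICU patient.

    Only the sepsis leaves contribute: patients who never develop sepsis
    carry no modelled in-hospital mortality (identical in both arms, so it
    cancels from every increment).
    """
    _check_arm(arm)
    leaves = leaf_probabilities(config.cohort.incidence, _arm_test(config, arm))
    t_tp, t_fn = arm_times(config, arm)
    total = 0.0
    for leaf_p, t in ((leaves.tp, t_tp), (leaves.fn, t_fn)):
        p_shock = shock_probability(config.shock_risk, t)
        total += leaf_p * (
            p_shock * mortality_shock(config.mortality, t)
            + (1 - p_shock) * mortality_nonshock(config.mortality, t)
        )
    return total


def sepsis_survivor_1yr(config: ModelConfig, arm: str) -> float:
    """Probability of being a sepsis patient alive 1 year after discharge.

    Septic-shock survivors are additionally exposed to the first-year
    post-discharge mortality; no-shock survivors are not.
    """
    _check_arm(arm)
    leaves = leaf_probabilities(config.cohort.incidence, _arm_test(config, arm))
    t_tp, t_fn = arm_times(config, arm)
    fym = config.postdischarge.postdischarge_mortality_year1_shock
    total = 0.0
    for leaf_p, t in ((leaves.tp, t_tp), (leaves.fn, t_fn)):
        p_shock = shock_probability(config.shock_risk, t)
        shock_surv = p_shock * (1 - mortality_shock(config.mortality, t))
        noshock_surv = (1 - p_shock) * (1 - mortality_nonshock(config.mortality, t))
        total += leaf_p * (shock_surv * (1 - fym) + noshock_surv)
    return total


def readmission_proportion(config: ModelConfig, arm: str) -> float:
    """Expected first-year readmission proportion per ICU patient.

    Default accounting applies the readmission rate to all in-hospital
    survivors; the ``sepsis_survivors`` option restricts it to surviving
    sepsis patients.
    """
    _check_arm(arm)
    rate = config.postdischarge.readmission_rate_year1
    if config.readmission_population == "sepsis_survivors":
        leaves = leaf_probabilities(config.cohort.incidence, _arm_test(config, arm))
        sepsis_deaths = in_hospital_mortality(config, arm)
        return rate * (leaves.tp + leaves.fn - sepsis_deaths)
    return rate * (1.0 - in_hospital_mortality(config, arm))


def _expected_qalys(
    config: ModelConfig, arm: str, life_table: LifeTable
) -> float:
    """Per-patient discounted QALYs over the model time horizon."""
    leaves = leaf_probabilities(config.cohort.incidence, _arm_test(config, arm))
    t_tp, t_fn = arm_times(config, arm)
    lt = config.longterm
    age = int(round(config.cohort.mean_age))
    proj_sepsis = project_survival(life_table, age, lt, apply_rr=True)
    proj_gen = project_survival(life_table, age, lt, apply_rr=False)
    q_shock = discounted_qalys(
        proj_sepsis,
        first_year_mortality=config.postdischarge.postdischarge_mortality_year1_shock,
    )
    q_noshock = discounted_qalys(proj_sepsis, first_year_mortality=0.0)
    q_gen = discounted_qalys(proj_gen)
    total = (leaves.tn + leaves.fp) * q_gen
    for leaf_p, t in ((leaves.tp, t_tp), (leaves.fn, t_fn)):
        p_shock = shock_probability(config.shock_risk, t)
        total += leaf_p * (
            p_shock * (1 - mortality_shock(config.mortality, t)) * q_shock
            + (1 - p_shock) * (1 - mortality_nonshock(config.mortality, t)) * q_noshock
        )
    return total


def _default_life_table() -> LifeTable:
    from .synthetic_data import default_life_table

    return default_life_table()


def evaluate_arm(
    config: ModelConfig, arm: str, life_table: LifeTable | None = None
) -> ArmOutcome:
    """Assemble all per-patient expectations and costs for one arm."""
    violations = validate_config(config)
    if violations:
        raise ValueError("invalid config: " + "; ".join(violations))
    _check_arm(arm)
    if life_table is None:
        life_table = _default_life_table()
    leaves = leaf_probabilities(config.cohort.incidence, _arm_test(config, arm))
    t_tp, t_fn = arm_times(config, arm)
    icu_days, ward_days = expected_los(config, arm)
    mortality = in_hospital_mortality(config, arm)
    readmit = readmission_proportion(config, arm)
    survivor_1yr = sepsis_survivor_1yr(config, arm)

    costs = config.costs
    cost_prediction = (
        costs.prediction_cost_per_patient if arm == "algorithm" else 0.0
    )
    cost_icu = icu_days * costs.icu_day
    cost_ward = ward_days * costs.ward_day
    cost_readmission = readmit * costs.readmission_event
    horizon = config.longterm.time_horizon_years
    include_lt = config.longterm.include_longterm_consequences and (
        horizon is None or horizon > 1
    )
    cost_longterm = (
        longterm_consequence_cost(survivor_1yr, costs.longterm_cost_per_survivor)
        if include_lt
        else 0.0
    )
    cost_total = (
        cost_prediction + cost_icu + cost_ward + cost_readmission + cost_longterm
    )
    return ArmOutcome(
        arm=arm,
        leaves=leaves,
        shock_probability_tp=shock_probability(config.shock_risk, t_tp),
        shock_probability_fn=shock_probability(config.shock_risk, t_fn),
        expected_icu_days=icu_days,
        expected_ward_days=ward_days,
        in_hospital_mortality=mortality,
        readmission_proportion=readmit,
        sepsis_survivor_1yr=survivor_1yr,
        cost_prediction=cost_prediction,
        cost_icu=cost_icu,
        cost_ward=cost_ward,
        cost_readmission=cost_readmission,
        cost_longterm=cost_longterm,
        cost_total=cost_total,
        qalys=_expected_qalys(config, arm, life_table),
    )


_DELTA_FIELDS = (
    "cost_prediction",
    "cost_icu",
    "cost_ward",
    "cost_readmission",
    "cost_longterm",
    "cost_total",
    "expected_icu_days",
    "expected_ward_days",
    "in_hospital_mortality",
    "readmission_proportion",
    "sepsis_survivor_1yr",
    "qalys",
)


def incremental(
    config: ModelConfig, life_table: LifeTable | None = None
) -> IncrementalResult:
    """Algorithm-minus-comparator differences and national scaling.

    National values are per-patient differences multiplied by the annual
    cohort of ICU admissions without sepsis; "saved" quantities (lives, ICU
    and ward days) are reported with a positive sign when the algorithm arm
    does better.
    """
    if life_table is None:
        life_table = _default_life_table()
    alg = evaluate_arm(config, "algorithm", life_table)
    comp = evaluate_arm(config, "comparator", life_table)
    n = config.cohort.n_icu_admissions_no_sepsis
    per_patient = {
        name: getattr(alg, name) - getattr(comp, name) for name in _DELTA_FIELDS
    }
    national = {name: value * n for name, value in per_patient.items()}
    return IncrementalResult(
        per_patient=per_patient,
        national=national,
        lives_saved_national=-per_patient["in_hospital_mortality"] * n,
        icu_days_saved_national=-per_patient["expected_icu_days"] * n,
        ward_days_saved_national=-per_patient["expected_ward_days"] * n,
        icer=icer(per_patient["cost_total"], per_patient["qalys"]),
        algorithm=alg,
        comparator=comp,
    )


def worked_example_prediction_cost(
    price_per_icu_day: float, expected_icu_days: float, incidence: float
) -> tuple[float, float]:
    """Per-patient and per-detected-sepsis-patient prediction cost.

    Prices the algorithm per ICU day (e.g. EUR 90/day at 1.62 expected ICU
    days gives about EUR 146 per ICU patient, or about EUR 1037 per sepsis
    patient detected once divided by the incidence).
    """
    if price_per_icu_day < 0 or expected_icu_days < 0:
        raise ValueError("price and days must be non-negative")
    if incidence <= 0:
        raise ValueError("incidence must be positive")
    per_patient = price_per_icu_day * expected_icu_days
    return per_patient, per_patient / incidence
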