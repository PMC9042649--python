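"""Model parameters: the complete input set for one model run.

``ModelConfig`` is the single source of truth for every model input: cohort
definition, screening-test characteristics for both arms, treatment-timing
policy, the time-dependent risk functions, lengths of stay, unit costs,
post-discharge and long-term parameters, and the probabilistic
sensitivity-analysis distribution table.  ``default_base_case()`` ships the
published Swedish ICU base case.

Three unit costs (ICU day, ward day, and the discounted lifetime
long-term-consequence cost per 1-year sepsis survivor) are not printed as
such in the source material; they are back-calculated from the published
per-arm cost and length-of-stay results (per-arm cost divided by per-arm
expected days, which agrees between arms to <0.1%) and shipped as fixed
defaults.
"""

from __future__ import annotations

import logging
from dataclasses import MISSING, asdict, dataclass, field, fields

import yaml

from .risk_models import MortalityCurves, ShockRiskLine

logger = logging.getLogger(__name__)

__all__ = [
    "CohortDefinition",
    "TestCharacteristics",
    "TimingPolicy",
    "LengthOfStayTable",
    "UnitCostTable",
    "PostDischargeParameters",
    "LongTermParameters",
    "DistributionSpec",
    "ModelConfig",
    "default_base_case",
    "validate_config",
    "load_config",
    "save_config",
]

# Back-calculated unit costs (EUR): published per-arm hospitalisation cost
# divided by per-arm expected days, averaged over the two arms (cross-arm
# agreement <0.1%); long-term lump likewise from the per-arm long-term cost
# row divided by the model's 1-year sepsis-survivor probability.
ICU_DAY_COST = 6355.38
WARD_DAY_COST = 626.26
LONGTERM_COST_PER_SURVIVOR = 1947.73


@dataclass
class CohortDefinition:
    """The modelled population: adult ICU admissions without sepsis at admission."""

    incidence: float = 0.141  # P(sepsis develops after ICU admission)
    mean_age: float = 60.0
    n_icu_admissions_total: int = 45_000  # per year, Sweden
    n_icu_admissions_no_sepsis: int = 36_900  # per year, eligible cohort


@dataclass
class TestCharacteristics:
    __test__ = False  # screening-test parameters, not a test-runner class

    sensitivity: float
    specificity: float


@dataclass
class TimingPolicy:
    """Total hours to treatment relative to current-practice diagnosis.

    ``t_tp`` applies to true positives in the algorithm arm (negative =
    earlier treatment); the comparator arm's true positives are treated at
    t = 0 by definition.  ``t_fn`` is the delay for false negatives in both
    arms.  ``t_antibiotic_from_detection`` shifts every pathway equally
    (0 in the base case: antibiotics start at detection).
    """

    t_tp: float = -3.0
    t_fn: float = 3.0
    t_antibiotic_from_detection: float = 0.0


@dataclass
class LengthOfStayTable:
    """Mean ICU and ward days per decision-tree leaf (days)."""

    icu_shock: float = 7.4
    icu_noshock: float = 2.0
    icu_true_negative: float = 1.0
    icu_false_positive: float = 2.0
    ward_shock: float = 17.0
    ward_noshock: float = 5.7
    ward_true_negative: float = 5.7
    ward_false_positive: float = 5.7


@dataclass
class UnitCostTable:
    icu_day: float = ICU_DAY_COST
    ward_day: float = WARD_DAY_COST
    readmission_event: float = 4166.0
    # charged once per ICU patient in the algorithm arm
    prediction_cost_per_patient: float = 1037.0
    # used only by the worked-example pricing operation
    prediction_price_per_icu_day: float = 90.0
    longterm_cost_per_survivor: float = LONGTERM_COST_PER_SURVIVOR


@dataclass
class PostDischargeParameters:
    readmission_rate_year1: float = 0.206  # all hospital survivors
    postdischarge_mortality_year1_shock: float = 0.175  # septic-shock survivors


@dataclass
class LongTermParameters:
    """Beyond-first-year survival, utility, and consequence parameters.

    Relative risks multiply the general-population annual death probability
    for sepsis survivors, by year since discharge (base-case values are the
    60-70 age band).  Utility decrements are added to ``baseline_utility``
    over the same bands.  ``time_horizon_years`` of ``None`` means lifetime
    (run the life table to exhaustion).
    """

    rr_years_1_5: float = 5.5
    rr_years_6_10: float = 3.1
    rr_years_11_plus: float = 1.0
    utility_decrement_years_1_5: float = -0.164
    utility_decrement_years_6_10: float = -0.124
    utility_decrement_years_11_plus: float = 0.0
    baseline_utility: float = 0.80
    discount_rate: float = 0.03
    consequence_frequencies: dict[str, float] = field(
        default_factory=lambda: {
            "impaired_kidney_function": 0.141,
            "amputation": 0.085,
            "depression": 0.028,
            "ptsd": 0.099,
        }
    )
    include_longterm_consequences: bool = True
    time_horizon_years: int | None = None
    max_age: int = 105


@dataclass
class DistributionSpec:
    """(family, mean, SE) specification of one stochastic parameter.

    ``se`` of 0 denotes a degenerate (constant) parameter, mirroring the
    published distribution table verbatim.
    """

    parameter_name: str
    family: str  # beta | gamma | lognormal | normal
    mean: float
    se: float


@dataclass
class ModelConfig:
    cohort: CohortDefinition = field(default_factory=CohortDefinition)
    algorithm_test: TestCharacteristics = field(
        default_factory=lambda: TestCharacteristics(0.80, 0.851)
    )
    comparator_test: TestCharacteristics = field(
        default_factory=lambda: TestCharacteristics(0.792, 0.785)
    )
    timing: TimingPolicy = field(default_factory=TimingPolicy)
    shock_risk: ShockRiskLine = field(default_factory=ShockRiskLine)
    mortality: MortalityCurves = field(default_factory=MortalityCurves)
    los: LengthOfStayTable = field(default_factory=LengthOfStayTable)
    costs: UnitCostTable = field(default_factory=UnitCostTable)
    postdischarge: PostDischargeParameters = field(
        default_factory=PostDischargeParameters
    )
    longterm: LongTermParameters = field(default_factory=LongTermParameters)
    psa_specs: list[DistributionSpec] = field(default_factory=list)
    wtp_thresholds: list[float] = field(default_factory=lambda: [20_000.0, 50_000.0])
    # "all_survivors" reproduces the published readmission accounting;
    # "sepsis_survivors" restricts readmission to sepsis patients.
    readmission_population: str = "all_survivors"


def _default_psa_specs() -> list[DistributionSpec]:
    """The published stochastic-analysis distribution table, row by row."""
    b, g, ln, n = "beta", "gamma", "lognormal", "normal"
    rows = [
        ("incidence", b, 0.141, 0.0038),
        ("sensitivity_algorithm", b, 0.80, 0.0183),
        ("specificity_algorithm", b, 0.851, 0.0068),
        ("sensitivity_comparator", b, 0.792, 0.0181),
        ("specificity_comparator", b, 0.785, 0.0063),
        ("hours_to_treatment_tp", n, -3.0, 0.5),
        ("hours_to_treatment_fn", n, 3.0, 0.5),
        ("hours_to_antibiotic", n, 0.0, 0.5),
        ("shock_probability_early", b, 0.40, 0.04),
        ("shock_probability_soc", b, 0.566, 0.0091),
        ("rr_mortality_shock", ln, 1.0, 0.255),
        ("rr_mortality_nonshock", ln, 1.0, 0.588),
        ("hr_years_1_5_under60", ln, 17.8, 2.653),
        ("hr_years_6_10_under60", ln, 6.0, 1.301),
        ("hr_years_1_5_60to70", ln, 5.5, 1.250),
        ("hr_years_6_10_60to70", ln, 3.1, 0.791),
        ("hr_years_1_5_over70", ln, 2.4, 0.791),
        ("hr_years_6_10_over70", ln, 1.8, 1.684),
        ("icu_days_shock", g, 7.4, 0.1989),
        ("icu_days_noshock", g, 2.0, 0.1650),
        ("icu_days_true_negative", g, 1.0, 0.0264),
        ("icu_days_false_positive", g, 2.0, 0.0264),
        ("ward_days_shock", g, 17.0, 0.4570),
        ("ward_days_noshock", g, 5.7, 0.4703),
        ("ward_days_true_negative", g, 5.7, 0.1505),
        ("ward_days_false_positive", g, 5.7, 0.1505),
        ("postdischarge_mortality_shock", b, 0.175, 0.0175),
        ("readmission_rate", b, 0.206, 0.0042),
        ("utility_decrement_years_1_5", n, -0.164, 0.0395),
        ("utility_decrement_years_6_10", n, -0.124, 0.0394),
        ("utility_decrement_years_11_plus", n, 0.0, 0.0),
        ("freq_impaired_kidney_function", b, 0.141, 0.0044),
        ("freq_amputation", b, 0.085, 0.0035),
        ("freq_depression", b, 0.028, 0.0021),
        ("freq_ptsd", b, 0.099, 0.0038),
    ]
    return [DistributionSpec(name, fam, mean, se) for name, fam, mean, se in rows]


def default_base_case() -> ModelConfig:
    """The published Swedish ICU base case, complete with PSA distributions."""
    cfg = ModelConfig()
    cfg.psa_specs = _default_psa_specs()
    return cfg


# ---------------------------------------------------------------------------
# Validation
# ---------------------------------------------------------------------------

def validate_config(config: ModelConfig) -> list[str]:
    """Return all invariant violations (empty list = valid config)."""
    v: list[str] = []
    c = config.cohort
    if not 0 < c.incidence < 1:
        v.append(f"cohort.incidence = {c.incidence} not in (0, 1)")
    if c.n_icu_admissions_total <= 0 or c.n_icu_admissions_no_sepsis <= 0:
        v.append("cohort admission counts must be positive")
    if c.n_icu_admissions_no_sepsis > c.n_icu_admissions_total:
        v.append("cohort.n_icu_admissions_no_sepsis exceeds total admissions")
    for arm, test in (("algorithm_test", config.algorithm_test),
                      ("comparator_test", config.comparator_test)):
        for name in ("sensitivity", "specificity"):
            val = getattr(test, name)
            if not 0 < val <= 1:
                v.append(f"{arm}.{name} = {val} not in (0, 1]")
    t = config.timing
    if t.t_fn < 0:
        v.append(f"timing.t_fn = {t.t_fn} must be >= 0")
    if t.t_tp > t.t_fn:
        v.append("timing.t_tp exceeds timing.t_fn")
    s = config.shock_risk
    if not 0 <= s.p_early <= s.p_ref <= 1:
        v.append("shock_risk requires 0 <= p_early <= p_ref <= 1")
    m = config.mortality
    if not 0 < m.a < 1:
        v.append(f"mortality.a = {m.a} not in (0, 1)")
    if m.b < 0 or m.c < 0:
        v.append("mortality.b and mortality.c must be >= 0")
    los = config.los
    for f in fields(los):
        if getattr(los, f.name) < 0:
            v.append(f"los.{f.name} is negative")
    if los.icu_shock < los.icu_noshock:
        v.append("los.icu_shock must be >= los.icu_noshock")
    costs = config.costs
    for f in fields(costs):
        if getattr(costs, f.name) < 0:
            v.append(f"costs.{f.name} is negative")
    pd_ = config.postdischarge
    if not 0 <= pd_.readmission_rate_year1 <= 1:
        v.append("postdischarge.readmission_rate_year1 not in [0, 1]")
    if not 0 <= pd_.postdischarge_mortality_year1_shock <= 1:
        v.append("postdischarge.postdischarge_mortality_year1_shock not in [0, 1]")
    lt = config.longterm
    for name in ("rr_years_1_5", "rr_years_6_10", "rr_years_11_plus"):
        if getattr(lt, name) < 1:
            v.append(f"longterm.{name} must be >= 1")
    if lt.discount_rate < 0:
        v.append("longterm.discount_rate must be >= 0")
    if not 0 < lt.baseline_utility <= 1:
        v.append("longterm.baseline_utility not in (0, 1]")
    for name, freq in lt.consequence_frequencies.items():
        if not 0 <= freq <= 1:
            v.append(f"longterm.consequence_frequencies[{name!r}] not in [0, 1]")
    if config.readmission_population not in ("all_survivors", "sepsis_survivors"):
        v.append(
            f"readmission_population {config.readmission_population!r} unknown"
        )
    for spec in config.psa_specs:
        if spec.family not in ("beta", "gamma", "lognormal", "normal"):
            v.append(f"psa_specs[{spec.parameter_name}]: unknown family {spec.family}")
            continue
        if spec.se < 0:
            v.append(f"psa_specs[{spec.parameter_name}]: se must be >= 0")
        if spec.family == "beta":
            if not 0 < spec.mean < 1:
                v.append(f"psa_specs[{spec.parameter_name}]: beta mean not in (0, 1)")
            elif spec.se ** 2 >= spec.mean * (1 - spec.mean):
                v.append(
                    f"psa_specs[{spec.parameter_name}]: beta moment condition "
                    f"violated (se^2 >= mean(1-mean))"
                )
        if spec.family in ("gamma", "lognormal") and spec.mean <= 0:
            v.append(f"psa_specs[{spec.parameter_name}]: mean must be > 0")
    return v


# ---------------------------------------------------------------------------
# Serialization (YAML; JSON-compatible structure)
# ---------------------------------------------------------------------------

_SECTION_TYPES = {
    "cohort": CohortDefinition,
    "algorithm_test": TestCharacteristics,
    "comparator_test": TestCharacteristics,
    "timing": TimingPolicy,
    "shock_risk": ShockRiskLine,
    "mortality": MortalityCurves,
    "los": LengthOfStayTable,
    "costs": UnitCostTable,
    "postdischarge": PostDischargeParameters,
    "longterm": LongTermParameters,
}


def config_to_dict(config: ModelConfig) -> dict:
    return asdict(config)


def _build_section(cls, data: dict, path: str):
    known = {f.name for f in fields(cls)}
    unknown = set(data) - known
    for key in sorted(unknown):
        logger.warning("ignoring unknown key %s.%s", path, key)
    # strict: config files must be complete even where code defaults exist
    missing = [f.name for f in fields(cls) if f.name not in data]
    if missing:
        raise KeyError(f"missing required field {path}.{missing[0]}")
    kwargs = {k: data[k] for k in known if k in data}
    return cls(**kwargs)


def config_from_dict(data: dict) -> ModelConfig:
    """Reconstruct a ModelConfig from a plain nested dict.

    A missing section or field is an error naming it; unknown keys are
    logged as warnings and ignored for forward compatibility.
    """
    if not isinstance(data, dict):
        raise ValueError("config root must be a mapping")
    cfg_fields = {f.name for f in fields(ModelConfig)}
    for key in sorted(set(data) - cfg_fields):
        logger.warning("ignoring unknown key %s", key)
    kwargs = {}
    for name, cls in _SECTION_TYPES.items():
        if name not in data:
            raise KeyError(f"missing required section {name!r}")
        section = data[name]
        if not isinstance(section, dict):
            raise ValueError(f"section {name!r} must be a mapping")
        kwargs[name] = _build_section(cls, section, name)
    specs = data.get("psa_specs", [])
    kwargs["psa_specs"] = [
        _build_section(DistributionSpec, row, f"psa_specs[{i}]")
        for i, row in enumerate(specs)
    ]
    if "wtp_thresholds" in data:
        kwargs["wtp_thresholds"] = [float(x) for x in data["wtp_thresholds"]]
    if "readmission_population" in data:
        kwargs["readmission_population"] = data["readmission_population"]
    return ModelConfig(**kwargs)


def save_config(config: ModelConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config_to_dict(config), fh, sort_keys=False)


def load_config(path) -> ModelConfig:
    """Load a YAML (or JSON — YAML is a superset) config file."""
    with open(path) as fh:
        try:
            data = yaml.safe_load(fh)
        except yaml.YAMLError as exc:
            raise ValueError(f"malformed config file {path}: {exc}") from exc
    return config_from_dict(data)
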