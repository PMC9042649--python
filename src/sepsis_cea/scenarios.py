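"""Deterministic one-way scenario analysis.

Each scenario overrides named configuration entries (absolute values or
multipliers on the base value), re-runs the full incremental model, and
reports the national annual cost impact together with its percent change
relative to the base case (negative impacts are savings; the percent
change uses the base impact as denominator, so a deeper saving shows as a
positive percentage, matching the published sign convention).

``preset_scenarios`` ships the full published scenario table: incidence
variants, alternative comparators (SOFA, NEWS2), reduced algorithm
specificity, detection lead times, septic-shock prevalence variants,
alternative in-hospital mortality models, lengths of stay and unit costs
+/-25%, post-discharge variants, and long-term-effect switches.
"""

from __future__ import annotations

import copy
from dataclasses import dataclass, field

import yaml

from .decision_tree import IncrementalResult, incremental
from .longterm import LifeTable
from .parameters import ModelConfig

__all__ = [
    "ScenarioSpec",
    "ScenarioResult",
    "apply_overrides",
    "run_scenario",
    "run_scenario_table",
    "preset_scenarios",
    "scenarios_from_yaml",
    "scenarios_to_yaml",
]


@dataclass
class ScenarioSpec:
    """A named set of config overrides.

    Override values are either plain values (assigned) or single-entry
    mappings ``{"multiply": factor}`` (scaled relative to the base value).
    Paths are dot-separated attribute paths into the config, e.g.
    ``"costs.icu_day"``.
    """

    name: str
    overrides: dict[str, object] = field(default_factory=dict)


@dataclass
class ScenarioResult:
    name: str
    national_cost_impact: float | None
    pct_change_vs_base: float | None
    per_patient_delta: float | None
    error: str | None = None


def _resolve(config: ModelConfig, path: str):
    parts = path.split(".")
    obj = config
    for part in parts[:-1]:
        if isinstance(obj, dict):
            if part not in obj:
                raise KeyError(f"unknown override path {path!r} (at {part!r})")
            obj = obj[part]
        elif hasattr(obj, part):
            obj = getattr(obj, part)
        else:
            raise KeyError(f"unknown override path {path!r} (at {part!r})")
    leaf = parts[-1]
    if isinstance(obj, dict):
        if leaf not in obj:
            raise KeyError(f"unknown override path {path!r} (at {leaf!r})")
    elif not hasattr(obj, leaf):
        raise KeyError(f"unknown override path {path!r} (at {leaf!r})")
    return obj, leaf


def _get(obj, leaf):
    return obj[leaf] if isinstance(obj, dict) else getattr(obj, leaf)


def _set(obj, leaf, value):
    if isinstance(obj, dict):
        obj[leaf] = value
    else:
        setattr(obj, leaf, value)


def apply_overrides(config: ModelConfig, spec: ScenarioSpec) -> ModelConfig:
    """Return a deep copy of the config with the scenario's overrides applied."""
    cfg = copy.deepcopy(config)
    for path, value in spec.overrides.items():
        obj, leaf = _resolve(cfg, path)
        if isinstance(value, dict):
            if set(value) != {"multiply"}:
                raise ValueError(
                    f"override {path!r}: mapping values must be {{'multiply': x}}"
                )
            _set(obj, leaf, _get(obj, leaf) * value["multiply"])
        else:
            _set(obj, leaf, value)
    return cfg


def run_scenario(
    config: ModelConfig,
    spec: ScenarioSpec,
    base: IncrementalResult | None = None,
    life_table: LifeTable | None = None,
) -> ScenarioResult:
    """Apply one scenario, re-run the model, and compare to the base case."""
    if base is None:
        base = incremental(config, life_table=life_table)
    cfg = apply_overrides(config, spec)
    result = incremental(cfg, life_table=life_table)
    impact = result.national["cost_total"]
    base_impact = base.national["cost_total"]
    pct = (
        (impact - base_impact) / base_impact * 100.0 if base_impact != 0 else None
    )
    return ScenarioResult(
        name=spec.name,
        national_cost_impact=impact,
        pct_change_vs_base=pct,
        per_patient_delta=result.per_patient["cost_total"],
    )


def run_scenario_table(
    config: ModelConfig,
    specs: list[ScenarioSpec] | None = None,
    life_table: LifeTable | None = None,
) -> list[ScenarioResult]:
    """Run a batch of scenarios; per-row failures are reported, not raised."""
    if specs is None:
        specs = preset_scenarios()
    base = incremental(config, life_table=life_table)
    results = []
    for spec in specs:
        try:
            results.append(run_scenario(config, spec, base=base, life_table=life_table))
        except Exception as exc:  # noqa: BLE001 - batch continues per row
            results.append(
                ScenarioResult(
                    name=spec.name,
                    national_cost_impact=None,
                    pct_change_vs_base=None,
                    per_patient_delta=None,
                    error=str(exc),
                )
            )
    return results


def preset_scenarios() -> list[ScenarioSpec]:
    """The published one-way scenario table, one spec per row."""
    los_mul = lambda f: {  # noqa: E731
        f"los.{name}": {"multiply": f}
        for name in (
            "icu_shock", "icu_noshock", "icu_true_negative", "icu_false_positive",
            "ward_shock", "ward_noshock", "ward_true_negative", "ward_false_positive",
        )
    }
    rows: list[tuple[str, dict[str, object]]] = [
        ("Incidence 30%", {"cohort.incidence": 0.30}),
        ("Incidence 20%", {"cohort.incidence": 0.20}),
        ("Incidence 10%", {"cohort.incidence": 0.10}),
        ("Comparator sensitivity and specificity: SOFA (80.0% / 48.0%)",
         {"comparator_test.sensitivity": 0.80, "comparator_test.specificity": 0.48}),
        ("Comparator sensitivity and specificity: NEWS2 (84.0% / 37.0%)",
         {"comparator_test.sensitivity": 0.84, "comparator_test.specificity": 0.37}),
        ("Algorithm specificity 78.5% (Sepsis-3)",
         {"algorithm_test.specificity": 0.785}),
        ("Detection 4 hours earlier", {"timing.t_tp": -4.0}),
        ("Detection 2 hours earlier", {"timing.t_tp": -2.0}),
        ("Detection 1 hour earlier", {"timing.t_tp": -1.0}),
        ("Proportion septic shock 30% at earlier detection",
         {"shock_risk.p_early": 0.30}),
        ("Proportion septic shock constant 56.6%",
         {"shock_risk.time_dependent": False}),
        ("In-hospital mortality: linear survival decrease 7.6%/hour",
         {"mortality.variant": "linear_survival"}),
        ("In-hospital mortality constant: 33% shock / 22% no shock",
         {"mortality.variant": "constant"}),
        ("Length of stay ICU and ward +25%", los_mul(1.25)),
        ("Length of stay ICU and ward -25%", los_mul(0.75)),
        ("Septic shock postdischarge mortality first year 0%",
         {"postdischarge.postdischarge_mortality_year1_shock": 0.0}),
        ("Readmission rate 0%", {"postdischarge.readmission_rate_year1": 0.0}),
        ("Readmission rate 40%", {"postdischarge.readmission_rate_year1": 0.40}),
        ("Unit cost of ICU and ward day +25%",
         {"costs.icu_day": {"multiply": 1.25}, "costs.ward_day": {"multiply": 1.25}}),
        ("Unit cost of ICU and ward day -25%",
         {"costs.icu_day": {"multiply": 0.75}, "costs.ward_day": {"multiply": 0.75}}),
        ("Unit cost of readmission +25%",
         {"costs.readmission_event": {"multiply": 1.25}}),
        ("Unit cost of readmission -25%",
         {"costs.readmission_event": {"multiply": 0.75}}),
        ("Long-term survival same as general population",
         {"longterm.rr_years_1_5": 1.0, "longterm.rr_years_6_10": 1.0,
          "longterm.rr_years_11_plus": 1.0}),
        ("Long-term consequences not included",
         {"longterm.include_longterm_consequences": False}),
        ("Model time horizon 1 year", {"longterm.time_horizon_years": 1}),
        ("Discount rate 0%", {"longterm.discount_rate": 0.0}),
    ]
    return [ScenarioSpec(name=n, overrides=o) for n, o in rows]


def scenarios_to_yaml(specs: list[ScenarioSpec], path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            [{"name": s.name, "overrides": s.overrides} for s in specs],
            fh, sort_keys=False,
        )


def scenarios_from_yaml(path) -> list[ScenarioSpec]:
    with open(path) as fh:
        data = yaml.safe_load(fh)
    if data is None:
        return []
    return [
        ScenarioSpec(name=row["name"], overrides=row.get("overrides", {}))
        for row in data
    ]
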