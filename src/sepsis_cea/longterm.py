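"""Beyond-first-year survival projection, discounted QALYs, and ICER.

Sepsis survivors carry an elevated long-term mortality, modelled as
band-wise relative risks on the general population's annual death
probability (5.5 in years 1-5 after discharge, 3.1 in years 6-10, 1.0 from
year 11 on, for the base-case age band), and a utility decrement over the
same bands.  QALYs are discounted annually at 3% with a year-end
convention.  Long-term consequence costs (impaired kidney function,
amputation, depression, PTSD) are carried as a single discounted lifetime
lump per sepsis patient alive one year after discharge.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .parameters import LongTermParameters

logger = logging.getLogger(__name__)

__all__ = [
    "LifeTable",
    "SurvivalProjection",
    "IcerResult",
    "project_survival",
    "discounted_qalys",
    "longterm_consequence_cost",
    "consequence_breakdown",
    "icer",
]


@dataclass
class LifeTable:
    """General-population annual death probabilities q(x) on an integer age grid."""

    ages: list[int]
    q: list[float]

    def __post_init__(self):
        if len(self.ages) != len(self.q):
            raise ValueError("ages and q must have equal length")

    @property
    def max_age(self) -> int:
        return self.ages[-1]

    def q_at(self, age: int) -> float:
        if age < self.ages[0] or age > self.max_age:
            raise ValueError(f"age {age} outside life table [{self.ages[0]}, {self.max_age}]")
        return self.q[age - self.ages[0]]

    def to_csv(self, path) -> None:
        pd.DataFrame({"age": self.ages, "qx": self.q}).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path) -> "LifeTable":
        df = pd.read_csv(path)
        return cls(ages=[int(a) for a in df["age"]], q=[float(x) for x in df["qx"]])


@dataclass
class SurvivalProjection:
    """Annual survival from the start age, with discounting and utilities.

    ``years`` counts years since hospital discharge (1, 2, ...);
    ``survival`` is the probability of being alive at the end of each year;
    ``discount`` the per-year factor (1+r)^-k; ``utility`` the health-state
    utility applied in that year.
    """

    start_age: int
    years: np.ndarray
    survival: np.ndarray
    hazard: np.ndarray
    discount: np.ndarray
    utility: np.ndarray


def _rr_for_year(lt: LongTermParameters, year: int) -> float:
    if year <= 5:
        return lt.rr_years_1_5
    if year <= 10:
        return lt.rr_years_6_10
    return lt.rr_years_11_plus


def _decrement_for_year(lt: LongTermParameters, year: int) -> float:
    if year <= 5:
        return lt.utility_decrement_years_1_5
    if year <= 10:
        return lt.utility_decrement_years_6_10
    return lt.utility_decrement_years_11_plus


def project_survival(
    life_table: LifeTable,
    start_age: int,
    longterm: LongTermParameters,
    apply_rr: bool = True,
) -> SurvivalProjection:
    """Project annual survival with band-wise relative risks on the life table.

    Year k uses hazard min(1, q(start_age + k - 1) * rr(k)).  With
    ``apply_rr`` False (general population, the no-sepsis pathways) the
    relative risk is 1 in every year and no utility decrement applies.
    """
    if start_age < life_table.ages[0] or start_age > life_table.max_age:
        raise ValueError(
            f"start_age {start_age} outside life table "
            f"[{life_table.ages[0]}, {life_table.max_age}]"
        )
    horizon = life_table.max_age - start_age
    if longterm.time_horizon_years is not None:
        horizon = min(horizon, longterm.time_horizon_years)
    horizon = max(horizon, 1)
    years = np.arange(1, horizon + 1)
    hazard = np.empty(horizon)
    utility = np.empty(horizon)
    for i, k in enumerate(years):
        rr = _rr_for_year(longterm, int(k)) if apply_rr else 1.0
        hazard[i] = min(1.0, life_table.q_at(start_age + int(k) - 1) * rr)
        dec = _decrement_for_year(longterm, int(k)) if apply_rr else 0.0
        u = longterm.baseline_utility + dec
        if u < 0:
            logger.warning("utility below 0 in year %d; clamped to 0", k)
            u = 0.0
        utility[i] = u
    survival = np.cumprod(1.0 - hazard)
    discount = (1.0 + longterm.discount_rate) ** (-years.astype(float))
    return SurvivalProjection(
        start_age=start_age,
        years=years,
        survival=survival,
        hazard=hazard,
        discount=discount,
        utility=utility,
    )


def discounted_qalys(
    projection: SurvivalProjection,
    in_hospital_death: bool = False,
    first_year_mortality: float | None = None,
) -> float:
    """Discounted QALYs for one hospital survivor (0 for in-hospital deaths).

    ``first_year_mortality`` (e.g. the 17.5% first-year post-discharge
    mortality of septic-shock survivors) replaces the projection's own
    year-1 hazard when given; ``None`` keeps the projection as is.  The
    year-end convention credits each year's utility to those alive at its
    end.
    """
    if in_hospital_death:
        return 0.0
    survival = projection.survival
    if first_year_mortality is not None:
        hazard = projection.hazard.copy()
        hazard[0] = first_year_mortality
        survival = np.cumprod(1.0 - hazard)
    return float(np.sum(survival * projection.utility * projection.discount))


def longterm_consequence_cost(
    sepsis_survivor_1yr: float, cost_per_survivor: float
) -> float:
    """Expected long-term consequence cost per ICU patient.

    ``sepsis_survivor_1yr`` is the probability of being a sepsis patient
    alive one year after discharge; ``cost_per_survivor`` the discounted
    lifetime lump applied to each such survivor.
    """
    if sepsis_survivor_1yr < 0 or cost_per_survivor < 0:
        raise ValueError("inputs must be non-negative")
    return sepsis_survivor_1yr * cost_per_survivor


def consequence_breakdown(
    longterm: LongTermParameters, sepsis_survivor_1yr: float
) -> dict[str, float]:
    """Expected per-patient frequency of each long-term consequence.

    Descriptive only: per-item costs are not published separately, so the
    cost side uses the single calibrated lump.
    """
    return {
        name: freq * sepsis_survivor_1yr
        for name, freq in longterm.consequence_frequencies.items()
    }


@dataclass
class IcerResult:
    """Incremental cost-effectiveness classification of (delta cost, delta QALY)."""

    delta_cost: float
    delta_qaly: float
    classification: str  # dominant | dominated | ratio | undefined
    ratio: float | None = None


def icer(delta_cost: float, delta_qaly: float) -> IcerResult:
    """Classify the incremental result by cost-effectiveness-plane quadrant.

    "Dominant" = cheaper and more effective; "dominated" = costlier and less
    effective; same-sign quadrants return the ratio delta cost / delta QALY.
    A zero QALY difference leaves the ratio undefined.
    """
    if delta_qaly == 0:
        return IcerResult(delta_cost, delta_qaly, "undefined")
    if delta_cost <= 0 and delta_qaly > 0:
        return IcerResult(delta_cost, delta_qaly, "dominant")
    if delta_cost > 0 and delta_qaly < 0:
        return IcerResult(delta_cost, delta_qaly, "dominated")
    return IcerResult(delta_cost, delta_qaly, "ratio", delta_cost / delta_qaly)
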