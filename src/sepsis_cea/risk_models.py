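"""Time-dependent septic-shock and in-hospital mortality risk functions.

The decision-tree model links the timing of sepsis treatment (hours relative
to current-practice diagnosis; negative = earlier) to two clinical risks:

* the probability of progressing to septic shock, modelled as a straight
  line through two anchor points (shock prevalence at current-practice
  timing and at an earlier detection time), and
* in-hospital mortality, modelled separately for patients with septic shock
  (exponential in time to treatment) and without (linear through the origin,
  floored at zero for earlier-than-practice treatment).

The module also implements the two-step procedure used to estimate the
mortality curves from grouped "delay-to-treatment vs cumulative mortality"
data: step 1 solves a linear program for monotone point estimates of the
cumulative mortality fraction on a time grid; step 2 fits the parametric
curve to those point estimates.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import linprog

__all__ = [
    "ShockRiskLine",
    "MortalityCurves",
    "GroupedMortalityData",
    "shock_probability",
    "mortality_shock",
    "mortality_nonshock",
    "estimate_mortality_points",
    "fit_mortality_curves",
]


def _clamp01(x: float) -> float:
    return min(1.0, max(0.0, x))


@dataclass
class ShockRiskLine:
    """Linear septic-shock prevalence in total hours to treatment.

    ``p_ref`` is the prevalence at t = 0 (current-practice diagnosis),
    ``p_early`` the prevalence at the earlier anchor ``t_early`` (< 0 hours).
    With ``time_dependent`` False the line degenerates to the constant
    ``p_ref`` (the "shock risk unaffected by timing" scenario).
    """

    p_ref: float = 0.566
    p_early: float = 0.40
    t_early: float = -3.0
    time_dependent: bool = True

    @property
    def slope(self) -> float:
        """Prevalence increase per hour of treatment delay."""
        if self.t_early == 0:
            return 0.0
        return (self.p_ref - self.p_early) / abs(self.t_early)


@dataclass
class MortalityCurves:
    """In-hospital mortality as a function of hours to treatment.

    The default variant is the pair of fitted curves a*exp(b*t) for septic
    shock and c*t (floored at 0) for sepsis without shock.  Two alternative
    variants are available for scenario analysis:

    * ``"linear_survival"`` — shock survival falls linearly with delay:
      mortality = anchor + slope*t (anchored at 40% mortality at t = 0,
      7.6 percentage points per hour by default);
    * ``"constant"`` — time-independent mortality (33% shock / 22% no shock
      by default).

    ``rr_shock_multiplier`` / ``rr_noshock_multiplier`` are relative-risk
    multipliers on the curve outputs used by the probabilistic sensitivity
    analysis (both 1.0 deterministically).
    """

    a: float = 0.4281
    b: float = 0.0272
    c: float = 0.0052
    rr_shock_multiplier: float = 1.0
    rr_noshock_multiplier: float = 1.0
    variant: str = "fitted"  # fitted | linear_survival | constant
    linear_anchor: float = 0.40
    linear_slope: float = 0.076
    constant_shock: float = 0.33
    constant_nonshock: float = 0.22


def shock_probability(line: ShockRiskLine, t: float) -> float:
    """Septic-shock probability at total hours to treatment ``t``.

    Clamped to [0, 1]; constant ``p_ref`` when the line is flagged
    time-independent.
    """
    if not line.time_dependent:
        return _clamp01(line.p_ref)
    return _clamp01(line.p_ref + line.slope * t)


def mortality_shock(curves: MortalityCurves, t: float) -> float:
    """In-hospital mortality for septic-shock patients at time ``t``."""
    if curves.variant == "constant":
        raw = curves.constant_shock
    elif curves.variant == "linear_survival":
        raw = curves.linear_anchor + curves.linear_slope * t
    else:
        raw = curves.a * math.exp(curves.b * t)
    return _clamp01(curves.rr_shock_multiplier * raw)


def mortality_nonshock(curves: MortalityCurves, t: float) -> float:
    """In-hospital mortality for sepsis patients without septic shock.

    The linear curve passes through the origin and is floored at 0 for
    negative ``t`` (earlier-than-practice treatment carries no sepsis
    mortality in this group).
    """
    if curves.variant == "constant":
        raw = curves.constant_nonshock
    else:
        raw = curves.c * t
    return _clamp01(curves.rr_noshock_multiplier * max(0.0, raw))


# ---------------------------------------------------------------------------
# Two-step estimation of the mortality curves from grouped data
# ---------------------------------------------------------------------------

@dataclass
class GroupedMortalityData:
    """Grouped delay-to-treatment vs cumulative mortality observations.

    Each row is a patient group whose treatment delay fell in
    [interval_start, interval_end) hours, with ``n_deaths`` of ``n_patients``
    dead in hospital.  ``grid`` lists the hour points at which the cumulative
    mortality fraction is to be estimated.
    """

    intervals: list[tuple[float, float, int, int]] = field(default_factory=list)
    grid: list[float] = field(default_factory=list)

    def validate(self) -> list[str]:
        problems = []
        prev_end = -math.inf
        for (s, e, n, d) in self.intervals:
            if e <= s:
                problems.append(f"interval [{s}, {e}) is empty or reversed")
            if s < prev_end:
                problems.append(f"interval [{s}, {e}) overlaps its predecessor")
            prev_end = e
            if n <= 0:
                problems.append(f"interval [{s}, {e}): n_patients {n} not positive")
            if d < 0 or d > n:
                problems.append(f"interval [{s}, {e}): n_deaths {d} outside [0, {n}]")
        return problems

    def to_csv(self, path) -> None:
        pd.DataFrame(
            self.intervals,
            columns=["interval_start", "interval_end", "n_patients", "n_deaths"],
        ).to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, grid=None) -> "GroupedMortalityData":
        df = pd.read_csv(path)
        rows = [
            (float(r.interval_start), float(r.interval_end),
             int(r.n_patients), int(r.n_deaths))
            for r in df.itertuples()
        ]
        if grid is None:
            grid = sorted({0.5 * (s + e) for (s, e, _, _) in rows})
        return cls(intervals=rows, grid=list(grid))


def estimate_mortality_points(
    data: GroupedMortalityData,
) -> list[tuple[float, float]]:
    """Step 1: monotone cumulative-mortality fractions on the grid, by LP.

    Decision variables are the mortality fractions m(t) at each grid hour.
    Each observed group's implied death count is n_patients times the mean
    of m over the grid points inside its interval; the LP minimises the
    total absolute deviation between implied and observed deaths subject to
    0 <= m <= 1 and m non-decreasing in t.  A tiny secondary penalty on
    sum(m) makes the solution unique when the data leave slack.
    """
    problems = data.validate()
    if problems:
        raise ValueError("invalid grouped mortality data: " + "; ".join(problems))
    grid = sorted(data.grid)
    k = len(grid)
    if k == 0:
        raise ValueError("empty evaluation grid")

    memberships = []
    for (s, e, n, d) in data.intervals:
        idx = [j for j, t in enumerate(grid) if s <= t < e]
        if not idx:
            # fall back to the grid point nearest the interval midpoint
            mid = 0.5 * (s + e)
            idx = [int(np.argmin([abs(t - mid) for t in grid]))]
        memberships.append(idx)

    m = len(data.intervals)
    # variables: m_1..m_k, then (u_i, v_i) absolute-deviation slacks per group
    n_var = k + 2 * m
    cost = np.zeros(n_var)
    cost[k::2] = 1.0  # u_i
    cost[k + 1::2] = 1.0  # v_i
    cost[:k] += 1e-9  # uniqueness tie-break: prefer the smallest monotone fit

    a_eq = np.zeros((m, n_var))
    b_eq = np.zeros(m)
    for i, ((s, e, n, d), idx) in enumerate(zip(data.intervals, memberships)):
        for j in idx:
            a_eq[i, j] = n / len(idx)
        a_eq[i, k + 2 * i] = -1.0  # implied - observed = u - v
        a_eq[i, k + 2 * i + 1] = 1.0
        b_eq[i] = d

    # monotonicity m_j - m_{j+1} <= 0
    a_ub = np.zeros((k - 1, n_var))
    for j in range(k - 1):
        a_ub[j, j] = 1.0
        a_ub[j, j + 1] = -1.0
    b_ub = np.zeros(k - 1)

    bounds = [(0.0, 1.0)] * k + [(0.0, None)] * (2 * m)
    res = linprog(
        cost,
        A_ub=a_ub if k > 1 else None,
        b_ub=b_ub if k > 1 else None,
        A_eq=a_eq,
        b_eq=b_eq,
        bounds=bounds,
        method="highs",
    )
    if not res.success:  # pragma: no cover - HiGHS solves all feasible inputs
        raise RuntimeError(f"mortality LP failed: {res.message}")
    return list(zip(grid, [float(x) for x in res.x[:k]]))


def fit_mortality_curves(
    points: list[tuple[float, float]],
    form: str,
) -> dict[str, float]:
    """Step 2: fit the parametric mortality curve to step-1 point estimates.

    ``form="exponential"`` fits a*exp(b*t) by ordinary least squares on the
    log scale (requires strictly positive mortalities); ``form=
    "linear_through_origin"`` fits c*t with the closed-form slope
    sum(t*y)/sum(t^2).  Returns the coefficient dict ({"a", "b"} or {"c"}).
    """
    if len(points) < 2:
        raise ValueError("need at least 2 points to fit a curve")
    t = np.array([p[0] for p in points], dtype=float)
    y = np.array([p[1] for p in points], dtype=float)
    if form == "exponential":
        bad = [p for p in points if p[1] <= 0]
        if bad:
            raise ValueError(
                f"exponential fit requires positive mortality; offending points: {bad}"
            )
        coef = np.polyfit(t, np.log(y), 1)
        return {"a": float(math.exp(coef[1])), "b": float(coef[0])}
    if form == "linear_through_origin":
        denom = float(np.sum(t * t))
        if denom == 0:
            raise ValueError("all time points are 0; slope undefined")
        return {"c": float(np.sum(t * y) / denom)}
    raise ValueError(f"unknown curve form {form!r}")
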