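"""Net present value of lifetime salary streams, scenario deltas, break-even.

NPV discounts the annual salary stream to constant 2025 dollars::

    beginning_of_year:  NPV = sum_t salary_t / (1 + r)**(t - 1)
    end_of_year:        NPV = sum_t salary_t / (1 + r)**t

The beginning-of-year convention (default) leaves the year-1 salary at
face value; the end-of-year value is exactly the beginning-of-year value
divided by (1 + r).

Three independent routes to the same number are provided: the
stream-based :func:`npv`, the vectorised kernel :func:`npv_draws` used
for Monte Carlo draws, and the piecewise-geometric closed form
:func:`scenario_npv_closed_form` (a geometric series per constant-rank,
constant-effort span of the career).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .career import (
    BASELINE,
    CareerPlan,
    EconomicParams,
    PromotionTrajectory,
    salary_stream,
)
from .compensation import SpecialtyRecord

__all__ = [
    "NPVSummary",
    "ScenarioDelta",
    "BreakevenResult",
    "BreakevenUnreachableError",
    "npv",
    "npv_draws",
    "scenario_npv",
    "scenario_npv_closed_form",
    "compare_to_baseline",
    "breakeven_additional_years",
]


@dataclass(frozen=True)
class NPVSummary:
    """One scenario NPV with its full parameterization."""

    specialty: str
    percentile: int
    trajectory: str
    variant: str
    params: EconomicParams
    npv: float


@dataclass(frozen=True)
class ScenarioDelta:
    """Scenario NPV minus the baseline-promotion NPV (same plan/params)."""

    specialty: str
    percentile: int
    trajectory: str
    variant: str
    npv: float
    baseline_npv: float
    delta_vs_baseline: float


class BreakevenUnreachableError(ValueError):
    """Career extension cannot close the NPV gap within the allowed years."""

    def __init__(self, max_extra: int, residual_gap: float):
        self.max_extra = max_extra
        self.residual_gap = residual_gap
        super().__init__(
            f"break-even not reachable within {max_extra} additional years; "
            f"residual NPV gap ${residual_gap:,.2f}"
        )


@dataclass(frozen=True)
class BreakevenResult:
    """Minimal whole-year career extension closing an NPV deficit.

    ``years`` is the smallest integer number of additional years such
    that the extended deficit-trajectory NPV reaches the reference NPV;
    ``years_fractional`` linearly pro-rates the final extension year's
    discounted salary.
    """

    years: int
    years_fractional: float
    deficit_npv: float
    reference_npv: float
    extended_npv: float


def npv(stream: np.ndarray, discount_rate: float, convention: str = "beginning_of_year") -> float:
    """Discount a cash-flow stream (year 1 first) to present value."""
    stream = np.asarray(stream, dtype=float)
    if stream.ndim != 1 or stream.size == 0:
        raise ValueError("stream must be a non-empty 1-D vector")
    if not discount_rate > -1:
        raise ValueError("discount_rate must exceed -1")
    exps = np.arange(stream.size, dtype=float)
    value = float((stream / (1.0 + discount_rate) ** exps).sum())
    if convention == "end_of_year":
        return value / (1.0 + discount_rate)
    if convention != "beginning_of_year":
        raise ValueError("convention must be beginning_of_year or end_of_year")
    return value


def _base_vector(
    record: SpecialtyRecord,
    percentile: int,
    trajectory: PromotionTrajectory,
    plan: CareerPlan,
) -> np.ndarray:
    """Effort-scaled starting salary by year: S_rank(t) * effort_t."""
    T = plan.career_years
    sal = np.array([record.salary(r, percentile) for r in trajectory.ranks(T)])
    return sal * plan.effort


def npv_draws(
    record: SpecialtyRecord,
    percentile: int,
    trajectory: PromotionTrajectory,
    plan: CareerPlan,
    growth: np.ndarray,
    discount: np.ndarray,
    convention: str = "beginning_of_year",
) -> np.ndarray:
    """Scenario NPV for paired vectors of (growth, discount) rates.

    Vectorised over draws; element i is the NPV under (growth[i],
    discount[i]) held constant over the whole career.
    """
    g = np.atleast_1d(np.asarray(growth, dtype=float))
    r = np.atleast_1d(np.asarray(discount, dtype=float))
    if g.shape != r.shape:
        raise ValueError("growth and discount vectors must have equal length")
    base = _base_vector(record, percentile, trajectory, plan)
    exps = np.arange(plan.career_years, dtype=float)
    stream = base[None, :] * (1.0 + g)[:, None] ** exps[None, :]
    values = (stream / (1.0 + r)[:, None] ** exps[None, :]).sum(axis=1)
    if convention == "end_of_year":
        values = values / (1.0 + r)
    elif convention != "beginning_of_year":
        raise ValueError("convention must be beginning_of_year or end_of_year")
    return values


def scenario_npv(
    record: SpecialtyRecord,
    percentile: int,
    trajectory: PromotionTrajectory,
    plan: CareerPlan,
    params: Optional[EconomicParams] = None,
) -> NPVSummary:
    """NPV of the lifetime earnings stream for one promotion scenario."""
    if params is None:
        params = EconomicParams()
    value = float(
        npv_draws(
            record,
            percentile,
            trajectory,
            plan,
            np.array([params.wage_growth]),
            np.array([params.discount_rate]),
            params.convention,
        )[0]
    )
    return NPVSummary(
        specialty=record.name,
        percentile=percentile,
        trajectory=trajectory.name,
        variant=plan.variant,
        params=params,
        npv=value,
    )


def scenario_npv_closed_form(
    record: SpecialtyRecord,
    percentile: int,
    trajectory: PromotionTrajectory,
    plan: CareerPlan,
    params: Optional[EconomicParams] = None,
) -> float:
    """Piecewise-geometric closed form of the scenario NPV.

    With x = (1+g)/(1+r), each maximal constant-rank, constant-effort
    span t = a..b contributes S * effort * (x**(a-1) - x**b) / (1 - x)
    (or S * effort * (b - a + 1) when x == 1).
    """
    if params is None:
        params = EconomicParams()
    g, r = params.wage_growth, params.discount_rate
    x = (1.0 + g) / (1.0 + r)
    T = plan.career_years
    ranks = trajectory.ranks(T)
    total = 0.0
    span_start = 0
    for t in range(1, T + 1):
        end_of_span = (
            t == T
            or ranks[t] != ranks[span_start]
            or plan.effort[t] != plan.effort[span_start]
        )
        if not end_of_span:
            continue
        a, b = span_start + 1, t
        s = record.salary(ranks[span_start], percentile) * plan.effort[span_start]
        if x == 1.0:
            total += s * (b - a + 1)
        else:
            total += s * (x ** (a - 1) - x**b) / (1.0 - x)
        span_start = t
    if params.convention == "end_of_year":
        total /= 1.0 + r
    return total


def compare_to_baseline(
    record: SpecialtyRecord,
    percentile: int,
    trajectory: PromotionTrajectory,
    plan: CareerPlan,
    params: Optional[EconomicParams] = None,
) -> ScenarioDelta:
    """Scenario NPV minus the baseline (7+7) promotion NPV."""
    if params is None:
        params = EconomicParams()
    scen = scenario_npv(record, percentile, trajectory, plan, params)
    base = scenario_npv(record, percentile, BASELINE, plan, params)
    return ScenarioDelta(
        specialty=record.name,
        percentile=percentile,
        trajectory=trajectory.name,
        variant=plan.variant,
        npv=scen.npv,
        baseline_npv=base.npv,
        delta_vs_baseline=scen.npv - base.npv,
    )


def breakeven_additional_years(
    record: SpecialtyRecord,
    percentile: int,
    deficit_trajectory: PromotionTrajectory,
    reference_trajectory: PromotionTrajectory,
    plan: CareerPlan,
    params: Optional[EconomicParams] = None,
    max_extra: int = 40,
) -> BreakevenResult:
    """Minimal career extension for a deficit trajectory to match a reference.

    Extension years continue at the deficit trajectory's final rank with
    wage growth g and full effort; the reference NPV is held at the
    original career length T. The extended NPV is non-decreasing in the
    number of extra years, so the first year reaching the reference is
    the minimum.

    Raises
    ------
    BreakevenUnreachableError
        If even ``max_extra`` additional years cannot close the gap
        (possible under heavy discounting, which caps the achievable
        extended NPV).
    """
    if params is None:
        params = EconomicParams()
    if max_extra < 1:
        raise ValueError("max_extra must be >= 1")
    g, r = params.wage_growth, params.discount_rate
    T = plan.career_years
    reference = scenario_npv(record, percentile, reference_trajectory, plan, params).npv
    deficit = scenario_npv(record, percentile, deficit_trajectory, plan, params).npv

    final_rank = deficit_trajectory.rank_at(T, T)
    s_final = record.salary(final_rank, percentile)
    end_factor = 1.0 / (1.0 + r) if params.convention == "end_of_year" else 1.0

    extended = deficit
    previous = deficit
    for extra in range(0, max_extra + 1):
        if extended >= reference:
            if extra == 0:
                frac = 0.0
            else:
                last_term = extended - previous
                frac = (extra - 1) + (reference - previous) / last_term
            return BreakevenResult(
                years=extra,
                years_fractional=frac,
                deficit_npv=deficit,
                reference_npv=reference,
                extended_npv=extended,
            )
        t = T + extra + 1  # next year to add
        term = s_final * (1.0 + g) ** (t - 1) / (1.0 + r) ** (t - 1) * end_factor
        previous = extended
        extended = extended + term
    raise BreakevenUnreachableError(max_extra, residual_gap=reference - previous)
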