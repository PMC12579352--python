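"""Promotion trajectories, career-length variants and the salary equation.

A career is modelled in whole years t = 1..T. A promotion trajectory
maps each career year to an academic rank: a years as assistant
professor, then b years as associate professor, then (optionally) full
professor for the remainder. Four named trajectories are standard:

========  ==============  ==============  ==========
name      assistant       associate       full
========  ==============  ==============  ==========
early     5 years         5 years         remainder
baseline  7 years         7 years         remainder
stalled   10 years        remainder       never
none      entire career   never           never
========  ==============  ==============  ==========

The salary in year t is the *current* starting salary for the rank held
that year, inflated by annual wage growth g from year 1::

    salary_t = S_rank(t) * (1 + g)**(t - 1) * effort_t

so on promotion in year k the salary jumps to the new rank's ladder at
its year-k level: the whole ladder inflates at g. Effort is 1.0 for a
standard career, 0.5 in the final 10 years for the part-time variant,
and the early-retirement variant shortens T by 10 years at full effort.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np

from .compensation import Rank, SpecialtyRecord

__all__ = [
    "PromotionTrajectory",
    "EARLY",
    "BASELINE",
    "STALLED",
    "NO_PROMOTION",
    "TRAJECTORIES",
    "CareerPlan",
    "CAREER_VARIANTS",
    "make_career_plan",
    "EconomicParams",
    "rank_at_year",
    "salary_at_year",
    "salary_stream",
]


@dataclass(frozen=True)
class PromotionTrajectory:
    """Year-to-rank mapping for one promotion pathway.

    ``assistant_years=None`` means assistant for the whole career (never
    promoted); ``associate_years=None`` means associate for the
    remainder (never full). ``reaches_full`` must be consistent with the
    year counts.
    """

    name: str
    assistant_years: Optional[int]
    associate_years: Optional[int]
    reaches_full: bool

    def __post_init__(self) -> None:
        a, b = self.assistant_years, self.associate_years
        if a is not None and a < 0:
            raise ValueError("assistant_years must be >= 0")
        if b is not None and b < 0:
            raise ValueError("associate_years must be >= 0")
        if a is None and b is not None:
            raise ValueError("assistant for the remainder precludes associate years")
        if self.reaches_full and (a is None or b is None):
            raise ValueError("reaching full professor requires finite assistant and associate spans")

    def rank_at(self, t: int, career_years: int) -> Rank:
        """Rank held in career year ``t`` (1-based), 1 <= t <= career_years."""
        if not 1 <= t <= career_years:
            raise ValueError(
                f"career year t={t} outside 1..{career_years} for trajectory {self.name!r}"
            )
        a = self.assistant_years
        if a is None or t <= a:
            return Rank.ASSISTANT
        b = self.associate_years
        if b is None or t <= a + b or not self.reaches_full:
            return Rank.ASSOCIATE
        return Rank.FULL

    def ranks(self, career_years: int) -> list[Rank]:
        return [self.rank_at(t, career_years) for t in range(1, career_years + 1)]


EARLY = PromotionTrajectory("early", 5, 5, True)
BASELINE = PromotionTrajectory("baseline", 7, 7, True)
STALLED = PromotionTrajectory("stalled", 10, None, False)
NO_PROMOTION = PromotionTrajectory("none", None, None, False)

#: The four standard trajectories, keyed by name.
TRAJECTORIES: dict[str, PromotionTrajectory] = {
    t.name: t for t in (EARLY, BASELINE, STALLED, NO_PROMOTION)
}

CAREER_VARIANTS = ("standard", "part_time", "early_retirement")

#: Length of the reduced-effort / retirement window, in years.
VARIANT_WINDOW_YEARS = 10
PART_TIME_EFFORT = 0.5


@dataclass(frozen=True)
class CareerPlan:
    """Career length T and per-year effort fractions (length-T vector)."""

    variant: str
    career_years: int
    effort: np.ndarray

    def __post_init__(self) -> None:
        if self.variant not in CAREER_VARIANTS:
            raise ValueError(f"variant must be one of {CAREER_VARIANTS}")
        eff = np.asarray(self.effort, dtype=float)
        if eff.shape != (self.career_years,):
            raise ValueError("effort vector length must equal career_years")
        if not np.all((eff > 0) & (eff <= 1)):
            raise ValueError("effort entries must lie in (0, 1]")
        object.__setattr__(self, "effort", eff)


def make_career_plan(variant: str, specialty_career_years: int) -> CareerPlan:
    """Build the career plan for a variant from a specialty's full-time T.

    * ``standard`` — T years at effort 1.0;
    * ``part_time`` — T years, effort 0.5 in the final 10 years;
    * ``early_retirement`` — T - 10 years at effort 1.0.
    """
    T = int(specialty_career_years)
    if variant == "standard":
        return CareerPlan("standard", T, np.ones(T))
    if variant == "part_time":
        if T <= VARIANT_WINDOW_YEARS:
            raise ValueError(
                f"part_time needs a career longer than {VARIANT_WINDOW_YEARS} years, got {T}"
            )
        eff = np.ones(T)
        eff[-VARIANT_WINDOW_YEARS:] = PART_TIME_EFFORT
        return CareerPlan("part_time", T, eff)
    if variant == "early_retirement":
        if T - VARIANT_WINDOW_YEARS < 1:
            raise ValueError(
                f"early_retirement needs career_years > {VARIANT_WINDOW_YEARS}, got {T}"
            )
        T2 = T - VARIANT_WINDOW_YEARS
        return CareerPlan("early_retirement", T2, np.ones(T2))
    raise ValueError(f"unknown career variant {variant!r}")


@dataclass(frozen=True)
class EconomicParams:
    """Wage growth g, discount rate r and the discounting convention.

    ``beginning_of_year`` (default) leaves the year-1 salary undiscounted,
    so the current starting salary enters at face value in constant 2025
    dollars; ``end_of_year`` discounts every year by one extra factor of
    (1 + r).
    """

    wage_growth: float = 0.03
    discount_rate: float = 0.04
    convention: str = "beginning_of_year"

    def __post_init__(self) -> None:
        if not self.wage_growth > -1:
            raise ValueError("wage_growth must exceed -1")
        if not self.discount_rate > -1:
            raise ValueError("discount_rate must exceed -1")
        if self.convention not in ("beginning_of_year", "end_of_year"):
            raise ValueError("convention must be beginning_of_year or end_of_year")

    @classmethod
    def from_mapping(cls, data: dict) -> "EconomicParams":
        allowed = {"wage_growth", "discount_rate", "convention"}
        unknown = set(data) - allowed
        if unknown:
            raise ValueError(f"unknown economic parameters: {sorted(unknown)}")
        return cls(**data)


def rank_at_year(trajectory: PromotionTrajectory, t: int, career_years: int) -> Rank:
    """Rank held in year ``t`` of a ``career_years``-year career."""
    return trajectory.rank_at(t, career_years)


def salary_at_year(
    record: SpecialtyRecord,
    percentile: int,
    trajectory: PromotionTrajectory,
    plan: CareerPlan,
    params: EconomicParams,
    t: int,
) -> float:
    """Salary in year t: S_rank(t) * (1+g)**(t-1) * effort_t (USD)."""
    rank = trajectory.rank_at(t, plan.career_years)
    s = record.salary(rank, percentile)
    return s * (1.0 + params.wage_growth) ** (t - 1) * float(plan.effort[t - 1])


def salary_stream(
    record: SpecialtyRecord,
    percentile: int,
    trajectory: PromotionTrajectory,
    plan: CareerPlan,
    params: Optional[EconomicParams] = None,
) -> np.ndarray:
    """Projected annual salaries over the modelled career (length T).

    Within a constant-rank, constant-effort span consecutive entries
    have ratio exactly (1 + g).
    """
    if params is None:
        params = EconomicParams()
    T = plan.career_years
    base = np.array(
        [record.salary(r, percentile) for r in trajectory.ranks(T)], dtype=float
    )
    exps = np.arange(T, dtype=float)
    return base * plan.effort * (1.0 + params.wage_growth) ** exps
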