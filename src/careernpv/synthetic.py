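"""Synthetic compensation schedules with survey-like structure.

The compensation survey underlying this kind of analysis is proprietary,
so the generator emulates its *structure* rather than its values: about
29 specialties, salaries for three ranks at three percentiles, strictly
increasing in rank at every percentile and in percentile at every rank,
with realistic inter-specialty spread. Monotonicity is enforced by
construction (multiplicative uplift factors > 1), because the model's
qualitative results — scenario dominance in particular — are stated for
rank-monotone salary ladders.

All salary values are synthetic; none is presented as a survey value.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional

import numpy as np

from .compensation import PERCENTILES, CompensationSchedule, Rank, SpecialtyRecord

__all__ = ["GeneratorConfig", "generate_compensation_table", "generate_worked_fixture"]

# Plausible academic pediatric subspecialty labels for synthetic schedules.
_SPECIALTY_NAMES = [
    "general_pediatrics",
    "emergency_medicine",
    "sports_medicine",
    "adolescent_medicine",
    "allergy_immunology",
    "cardiology",
    "cardiac_critical_care",
    "child_abuse",
    "critical_care",
    "developmental_behavioral",
    "endocrinology",
    "gastroenterology",
    "genetics",
    "hematology_oncology",
    "hospital_medicine",
    "infectious_diseases",
    "neonatology",
    "nephrology",
    "neurology",
    "palliative_care",
    "pulmonology",
    "rheumatology",
    "sleep_medicine",
    "transplant_hepatology",
    "urgent_care",
    "pain_medicine",
    "medical_toxicology",
    "epilepsy",
    "hospice_care",
    "complex_care",
]


@dataclass(frozen=True)
class GeneratorConfig:
    """Knobs for the synthetic schedule generator.

    Defaults: assistant-professor 50th-percentile salaries uniform on
    $140k-$260k; each rank step multiplies salary by a factor in
    [1.08, 1.30]; the 75th/50th and 50th/25th percentile ratios lie in
    [1.06, 1.22]; two 38-year specialties and one 37-year specialty,
    the rest 35 years.
    """

    n_specialties: int = 29
    seed: Optional[int] = None
    assistant_median_range: tuple[float, float] = (140_000.0, 260_000.0)
    rank_uplift_range: tuple[float, float] = (1.08, 1.30)
    percentile_spread_range: tuple[float, float] = (1.06, 1.22)
    #: counts of specialties with non-default career lengths; the rest get 35.
    career_years_counts: Mapping[int, int] = field(
        default_factory=lambda: {38: 2, 37: 1}
    )

    def __post_init__(self) -> None:
        if self.n_specialties < 1:
            raise ValueError("n_specialties must be >= 1")
        for name, (lo, hi) in (
            ("assistant_median_range", self.assistant_median_range),
            ("rank_uplift_range", self.rank_uplift_range),
            ("percentile_spread_range", self.percentile_spread_range),
        ):
            if not (0 < lo < hi):
                raise ValueError(f"{name} must be a positive interval with lower < upper")
        if self.rank_uplift_range[0] <= 1:
            raise ValueError("rank uplifts must exceed 1 (monotone in rank)")
        if self.percentile_spread_range[0] <= 1:
            raise ValueError("percentile spreads must exceed 1 (monotone in percentile)")
        if any(c < 0 for c in self.career_years_counts.values()):
            raise ValueError("career_years_counts must be non-negative")


def _career_years_vector(config: GeneratorConfig) -> list[int]:
    # longest careers first; truncated when n_specialties is small
    years: list[int] = []
    for y, count in sorted(config.career_years_counts.items(), reverse=True):
        years.extend([y] * count)
    years = years[: config.n_specialties]
    years.extend([35] * (config.n_specialties - len(years)))
    return years


def generate_compensation_table(config: GeneratorConfig = GeneratorConfig()) -> CompensationSchedule:
    """Generate a rank- and percentile-monotone synthetic schedule.

    Deterministic for a fixed ``config.seed``; strictly monotone by
    construction, so it passes ``validate_monotonicity`` with zero
    warnings. Salaries are rounded to the cent.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_specialties
    names = list(_SPECIALTY_NAMES[:n])
    names += [f"subspecialty_{i:02d}" for i in range(len(names) + 1, n + 1)]
    career_years = _career_years_vector(config)

    records = []
    for name, years in zip(names, career_years):
        p50_assistant = rng.uniform(*config.assistant_median_range)
        uplift = rng.uniform(*config.rank_uplift_range, size=2)  # asst->assoc, assoc->full
        spread = rng.uniform(*config.percentile_spread_range, size=2)  # 50/25, 75/50
        by_rank = {
            Rank.ASSISTANT: p50_assistant,
            Rank.ASSOCIATE: p50_assistant * uplift[0],
            Rank.FULL: p50_assistant * uplift[0] * uplift[1],
        }
        salaries = {}
        for rank, p50 in by_rank.items():
            salaries[(rank, 25)] = round(p50 / spread[0], 2)
            salaries[(rank, 50)] = round(p50, 2)
            salaries[(rank, 75)] = round(p50 * spread[1], 2)
        records.append(SpecialtyRecord(name, years, salaries))
    return CompensationSchedule(records=records, source="synthetic-generator")


def generate_worked_fixture() -> CompensationSchedule:
    """Frozen two-specialty schedule with round-number salaries.

    Used by worked examples and brute-force oracles. Specialty "alpha"
    (T = 35) has 50th-percentile salaries 100 000 / 120 000 / 150 000
    for assistant/associate/full; "beta" (T = 38) is 1.5x alpha.
    Percentile spread is +/-10% around the 50th at every rank.
    """

    def cells(base: tuple[float, float, float]) -> dict:
        out = {}
        for rank, s in zip(Rank, base):
            out[(rank, 25)] = round(s * 0.9, 2)
            out[(rank, 50)] = float(s)
            out[(rank, 75)] = round(s * 1.1, 2)
        return out

    alpha = SpecialtyRecord("alpha", 35, cells((100_000.0, 120_000.0, 150_000.0)))
    beta = SpecialtyRecord("beta", 38, cells((150_000.0, 180_000.0, 225_000.0)))
    return CompensationSchedule(records=[alpha, beta], source="worked-fixture")
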