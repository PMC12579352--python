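"""Compensation schedule data model and CSV round-trip.

The model's only empirical input is a table of *starting* salaries, in
constant 2025 US dollars, for each specialty at three academic ranks
(assistant, associate, full professor) and three salary percentiles
(25th, 50th, 75th), plus a per-specialty full-time career length in
years. The on-disk format is a long CSV with one row per
(specialty, rank, percentile) cell::

    specialty,career_years,rank,percentile,salary
    cardiology,35,assistant,50,210000.00

A specialty is admitted only when all nine rank x percentile cells are
present — mirroring the inclusion rule of compensation surveys that
require complete data across ranks. Salaries are carried to the cent and
never rounded internally.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import pandas as pd
import yaml

__all__ = [
    "Rank",
    "PERCENTILES",
    "SpecialtyRecord",
    "CompensationSchedule",
    "ScheduleError",
    "IncompleteSpecialtyError",
    "DuplicateCellError",
    "read_compensation_csv",
    "write_compensation_csv",
    "validate_monotonicity",
    "load_params_config",
]

#: Admitted salary percentiles of the compensation survey.
PERCENTILES: tuple[int, ...] = (25, 50, 75)

#: Default full-time career length (years) when the CSV omits the column.
DEFAULT_CAREER_YEARS = 35

CSV_COLUMNS = ["specialty", "career_years", "rank", "percentile", "salary"]


class Rank(enum.IntEnum):
    """Academic rank, totally ordered assistant < associate < full."""

    ASSISTANT = 1
    ASSOCIATE = 2
    FULL = 3

    @classmethod
    def parse(cls, value: "str | int | Rank") -> "Rank":
        if isinstance(value, Rank):
            return value
        if isinstance(value, str):
            key = value.strip().lower()
            aliases = {
                "assistant": cls.ASSISTANT,
                "associate": cls.ASSOCIATE,
                "full": cls.FULL,
            }
            if key in aliases:
                return aliases[key]
            raise ValueError(f"unknown rank {value!r}; expected assistant|associate|full")
        return cls(value)

    @property
    def label(self) -> str:
        return self.name.lower()


def _check_percentile(percentile: int) -> int:
    p = int(percentile)
    if p not in PERCENTILES:
        raise ValueError(f"percentile must be one of {PERCENTILES}, got {percentile!r}")
    return p


class ScheduleError(ValueError):
    """Base class for compensation-schedule validation failures."""


class IncompleteSpecialtyError(ScheduleError):
    """A specialty is missing one or more of its 9 rank x percentile cells."""

    def __init__(self, missing: Mapping[str, list[tuple[str, int]]]):
        self.missing = dict(missing)
        parts = [
            f"{name}: missing {', '.join(f'{r}/{p}' for r, p in cells)}"
            for name, cells in self.missing.items()
        ]
        super().__init__(
            "incomplete compensation data (specialties need all 9 rank x percentile "
            "cells): " + "; ".join(parts)
        )


class DuplicateCellError(ScheduleError):
    """The same (specialty, rank, percentile) cell appears more than once."""

    def __init__(self, cells: list[tuple[str, str, int]]):
        self.cells = list(cells)
        listing = ", ".join(f"{s}/{r}/{p}" for s, r, p in self.cells)
        super().__init__(f"duplicate compensation rows for: {listing}")


@dataclass(frozen=True)
class SpecialtyRecord:
    """Starting salaries for one specialty across ranks and percentiles.

    Parameters
    ----------
    name
        Specialty label (free text, unique within a schedule).
    career_years
        Full-time career length T in years (38 for general pediatrics and
        emergency medicine, 37 for sports medicine, 35 otherwise).
    salaries
        Mapping ``(Rank, percentile) -> starting salary`` in constant
        2025 USD; all nine cells must be present and positive.
    """

    name: str
    career_years: int
    salaries: Mapping[tuple[Rank, int], float]

    def __post_init__(self) -> None:
        if int(self.career_years) < 1:
            raise ScheduleError(f"{self.name}: career_years must be >= 1")
        object.__setattr__(self, "career_years", int(self.career_years))
        cells = {(Rank.parse(r), _check_percentile(p)): float(s) for (r, p), s in self.salaries.items()}
        expected = {(r, p) for r in Rank for p in PERCENTILES}
        missing = sorted(expected - cells.keys())
        if missing:
            raise IncompleteSpecialtyError(
                {self.name: [(r.label, p) for r, p in missing]}
            )
        extra = cells.keys() - expected
        if extra:
            raise ScheduleError(f"{self.name}: unexpected salary cells {sorted(extra)}")
        for (r, p), s in cells.items():
            if not s > 0:
                raise ScheduleError(
                    f"{self.name}: non-positive salary {s} at {r.label}/{p}"
                )
        object.__setattr__(self, "salaries", cells)

    def salary(self, rank: "Rank | str", percentile: int) -> float:
        """Starting salary for ``rank`` at ``percentile`` (constant 2025 USD)."""
        return self.salaries[(Rank.parse(rank), _check_percentile(percentile))]


@dataclass
class CompensationSchedule:
    """An ordered collection of :class:`SpecialtyRecord`, unique by name."""

    records: list[SpecialtyRecord] = field(default_factory=list)
    currency_year: str = "2025"
    source: str = "synthetic"

    def __post_init__(self) -> None:
        if not self.records:
            raise ScheduleError("schedule must contain at least one specialty")
        names = [r.name for r in self.records]
        dupes = sorted({n for n in names if names.count(n) > 1})
        if dupes:
            raise ScheduleError(f"duplicate specialty names: {dupes}")

    def __len__(self) -> int:
        return len(self.records)

    def __iter__(self) -> Iterator[SpecialtyRecord]:
        return iter(self.records)

    def __getitem__(self, name: str) -> SpecialtyRecord:
        for rec in self.records:
            if rec.name == name:
                return rec
        raise KeyError(name)

    @property
    def specialties(self) -> list[str]:
        return [r.name for r in self.records]

    def to_frame(self) -> pd.DataFrame:
        """Long-format view: one row per (specialty, rank, percentile)."""
        rows = [
            {
                "specialty": rec.name,
                "career_years": rec.career_years,
                "rank": rank.label,
                "percentile": pct,
                "salary": rec.salaries[(rank, pct)],
            }
            for rec in self.records
            for rank in Rank
            for pct in PERCENTILES
        ]
        return pd.DataFrame(rows, columns=CSV_COLUMNS)


def _schedule_from_frame(df: pd.DataFrame, source: str) -> CompensationSchedule:
    missing_cols = [c for c in CSV_COLUMNS if c not in df.columns and c != "career_years"]
    if missing_cols:
        raise ScheduleError(f"missing required columns: {missing_cols}")
    df = df.copy()
    if "career_years" not in df.columns:
        df["career_years"] = DEFAULT_CAREER_YEARS
    df["career_years"] = df["career_years"].fillna(DEFAULT_CAREER_YEARS).astype(int)
    df["rank"] = df["rank"].map(lambda v: Rank.parse(v))
    df["percentile"] = df["percentile"].astype(int).map(_check_percentile)
    df["salary"] = df["salary"].astype(float)

    dup_mask = df.duplicated(subset=["specialty", "rank", "percentile"], keep=False)
    if dup_mask.any():
        dupes = sorted(
            {
                (row.specialty, Rank(row.rank).label, int(row.percentile))
                for row in df[dup_mask].itertuples()
            }
        )
        raise DuplicateCellError(dupes)

    incomplete: dict[str, list[tuple[str, int]]] = {}
    records: list[SpecialtyRecord] = []
    # preserve first-appearance order of specialties
    for name in df["specialty"].drop_duplicates():
        sub = df[df["specialty"] == name]
        cells = {
            (Rank(row.rank), int(row.percentile)): float(row.salary)
            for row in sub.itertuples()
        }
        expected = {(r, p) for r in Rank for p in PERCENTILES}
        missing = sorted(expected - cells.keys())
        if missing:
            incomplete[str(name)] = [(r.label, p) for r, p in missing]
            continue
        years = sub["career_years"].iloc[0]
        if sub["career_years"].nunique() > 1:
            raise ScheduleError(f"{name}: inconsistent career_years values")
        records.append(SpecialtyRecord(str(name), int(years), cells))
    if incomplete:
        raise IncompleteSpecialtyError(incomplete)
    return CompensationSchedule(records=records, source=source)


def read_compensation_csv(path: "str | Path") -> CompensationSchedule:
    """Read a long-format compensation CSV into a validated schedule.

    Raises
    ------
    IncompleteSpecialtyError
        If any specialty lacks one of its 9 rank x percentile cells.
    DuplicateCellError
        If a (specialty, rank, percentile) cell appears more than once.
    ScheduleError
        For missing columns, non-positive salaries, or inconsistent
        career lengths.
    """
    path = Path(path)
    df = pd.read_csv(path)
    return _schedule_from_frame(df, source=str(path))


def write_compensation_csv(schedule: CompensationSchedule, path: "str | Path") -> Path:
    """Write the schedule to CSV; round-trips exactly (salaries to the cent)."""
    path = Path(path)
    df = schedule.to_frame()
    df.to_csv(path, index=False, float_format="%.2f")
    return path


def validate_monotonicity(schedule: CompensationSchedule) -> list[str]:
    """Warn (never fail) where salaries are not strictly increasing.

    Checks every adjacent rank step at fixed percentile and every
    adjacent percentile step at fixed rank; real survey data can contain
    inversions, so violations are reported as warning strings rather
    than raised.
    """
    warnings: list[str] = []
    rank_steps = list(zip(list(Rank)[:-1], list(Rank)[1:]))
    pct_steps = list(zip(PERCENTILES[:-1], PERCENTILES[1:]))
    for rec in schedule:
        for pct in PERCENTILES:
            for lo, hi in rank_steps:
                if not rec.salary(hi, pct) > rec.salary(lo, pct):
                    warnings.append(
                        f"{rec.name}: salary not increasing {lo.label}->{hi.label} "
                        f"at percentile {pct}"
                    )
        for rank in Rank:
            for lo, hi in pct_steps:
                if not rec.salary(rank, hi) > rec.salary(rank, lo):
                    warnings.append(
                        f"{rec.name}: salary not increasing percentile {lo}->{hi} "
                        f"at rank {rank.label}"
                    )
    return warnings


def load_params_config(path: "str | Path") -> dict:
    """Load economic-parameter defaults from a YAML (or JSON) config file."""
    with open(path, "r", encoding="utf-8") as fh:
        data = yaml.safe_load(fh)
    if not isinstance(data, dict):
        raise ScheduleError(f"config file {path} must contain a mapping")
    return data
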