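"""Cross-specialty aggregation tables and the full report bundle.

Aggregates per-specialty scenario NPVs into the statistics a reader
would see in a scenario-comparison figure set: per-specialty deltas vs
the baseline promotion pathway, box-plot summaries (median, quartiles,
min/max) across specialties per percentile and per career-length
variant, one-way sensitivity sweep tables, and Monte Carlo summaries.

Quartiles use linear interpolation between closest ranks (numpy's
default ``linear`` method); whiskers are min/max. Every table embeds
its full parameterization so any number can be recomputed by calling
the underlying operation.
"""

from __future__ import annotations

import json
import shutil
import tempfile
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import __version__
from .career import (
    BASELINE,
    EARLY,
    NO_PROMOTION,
    STALLED,
    CAREER_VARIANTS,
    EconomicParams,
    PromotionTrajectory,
    TRAJECTORIES,
    make_career_plan,
)
from .compensation import PERCENTILES, CompensationSchedule
from .npv import compare_to_baseline, scenario_npv
from .uncertainty import (
    DEFAULT_DISCOUNT_SPEC,
    DEFAULT_GROWTH_SPEC,
    discount_rate_sweep_spec,
    pooled_mc_summary,
    sweep,
    wage_growth_sweep_spec,
)

__all__ = [
    "delta_table",
    "box_stats",
    "cross_percentile_comparison",
    "ReportConfig",
    "run_full_report",
]

_ALL_TRAJECTORIES = (EARLY, BASELINE, STALLED, NO_PROMOTION)
_NONBASELINE = (EARLY, STALLED, NO_PROMOTION)


def delta_table(
    schedule: CompensationSchedule,
    percentile: int = 50,
    variant: str = "standard",
    params: Optional[EconomicParams] = None,
    trajectories: Sequence[PromotionTrajectory] = _NONBASELINE,
) -> pd.DataFrame:
    """Per-specialty NPV differences vs baseline promotion.

    One row per (specialty, trajectory); on rank-monotone schedules the
    early delta is positive and the stalled / no-promotion deltas are
    negative.
    """
    if params is None:
        params = EconomicParams()
    rows = []
    for rec in schedule:
        plan = make_career_plan(variant, rec.career_years)
        for traj in trajectories:
            d = compare_to_baseline(rec, percentile, traj, plan, params)
            rows.append(
                {
                    "specialty": d.specialty,
                    "trajectory": d.trajectory,
                    "percentile": d.percentile,
                    "variant": d.variant,
                    "npv": d.npv,
                    "baseline_npv": d.baseline_npv,
                    "delta_vs_baseline": d.delta_vs_baseline,
                }
            )
    return pd.DataFrame(rows)


def box_stats(
    schedule: CompensationSchedule,
    trajectories: Sequence[PromotionTrajectory] = _ALL_TRAJECTORIES,
    percentiles: Sequence[int] = PERCENTILES,
    variants: Sequence[str] = ("standard",),
    params: Optional[EconomicParams] = None,
) -> pd.DataFrame:
    """Across-specialty NPV box statistics per (variant, percentile, trajectory).

    Median by the standard midpoint rule; quartiles by linear
    interpolation between closest ranks; whiskers are min and max.
    """
    if params is None:
        params = EconomicParams()
    rows = []
    for variant in variants:
        for pct in percentiles:
            for traj in trajectories:
                values = np.array(
                    [
                        scenario_npv(
                            rec, pct, traj, make_career_plan(variant, rec.career_years), params
                        ).npv
                        for rec in schedule
                    ]
                )
                q1, med, q3 = np.percentile(values, [25, 50, 75])
                rows.append(
                    {
                        "variant": variant,
                        "percentile": pct,
                        "trajectory": traj.name,
                        "median": float(med),
                        "q1": float(q1),
                        "q3": float(q3),
                        "min": float(values.min()),
                        "max": float(values.max()),
                        "n_specialties": len(schedule),
                    }
                )
    return pd.DataFrame(rows)


def cross_percentile_comparison(
    schedule: CompensationSchedule,
    promoted: PromotionTrajectory = BASELINE,
    promoted_percentile: int = 25,
    unpromoted: PromotionTrajectory = NO_PROMOTION,
    unpromoted_percentile: int = 75,
    variant: str = "standard",
    params: Optional[EconomicParams] = None,
) -> pd.DataFrame:
    """Does promotion outweigh salary percentile, specialty by specialty?

    Compares the promoted trajectory at a *lower* salary percentile
    against the unpromoted trajectory at a *higher* percentile. The
    crossover (promoted-at-25th beating never-promoted-at-75th) occurs
    when the rank salary uplift is large relative to the percentile
    spread; it is a property of the data, not a universal theorem.
    """
    if params is None:
        params = EconomicParams()
    rows = []
    for rec in schedule:
        plan = make_career_plan(variant, rec.career_years)
        lo = scenario_npv(rec, promoted_percentile, promoted, plan, params).npv
        hi = scenario_npv(rec, unpromoted_percentile, unpromoted, plan, params).npv
        rows.append(
            {
                "specialty": rec.name,
                "promoted_trajectory": promoted.name,
                "promoted_percentile": promoted_percentile,
                "promoted_npv": lo,
                "unpromoted_trajectory": unpromoted.name,
                "unpromoted_percentile": unpromoted_percentile,
                "unpromoted_npv": hi,
                "crossover": lo > hi,
            }
        )
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class ReportConfig:
    """Parameterization of a full report run (embedded in the manifest)."""

    params: EconomicParams = field(default_factory=EconomicParams)
    percentiles: tuple[int, ...] = PERCENTILES
    variants: tuple[str, ...] = CAREER_VARIANTS
    delta_percentile: int = 50
    mc_percentile: int = 50
    n_iter: int = 10_000
    seed: int = 0


def run_full_report(
    schedule: CompensationSchedule,
    out_dir: "str | Path",
    config: ReportConfig = ReportConfig(),
) -> dict[str, Path]:
    """Write the full table bundle; deterministic under a fixed seed.

    Outputs (CSV unless noted): ``deltas.csv`` (per-specialty deltas vs
    baseline), ``box_by_percentile.csv`` (standard career, all
    percentiles), ``box_by_career.csv`` (all career variants),
    ``sweep_growth.csv`` / ``sweep_discount.csv`` (one-way sweeps),
    ``mc_summary.csv`` (pooled Monte Carlo), and ``manifest.json``. The
    bundle is written atomically: on failure no partial output is left
    behind.
    """
    out_dir = Path(out_dir)
    tmp = Path(tempfile.mkdtemp(prefix="careernpv-report-", dir=out_dir.parent if out_dir.parent.exists() else None))
    try:
        tables: dict[str, pd.DataFrame] = {}
        tables["deltas"] = delta_table(
            schedule, config.delta_percentile, "standard", config.params
        )
        tables["box_by_percentile"] = box_stats(
            schedule, percentiles=config.percentiles, variants=("standard",), params=config.params
        )
        tables["box_by_career"] = box_stats(
            schedule,
            percentiles=(config.delta_percentile,),
            variants=config.variants,
            params=config.params,
        )
        tables["sweep_growth"] = sweep(
            schedule, config.delta_percentile, wage_growth_sweep_spec(),
            convention=config.params.convention,
        )
        tables["sweep_discount"] = sweep(
            schedule, config.delta_percentile, discount_rate_sweep_spec(),
            convention=config.params.convention,
        )
        tables["mc_summary"] = pooled_mc_summary(
            schedule,
            config.mc_percentile,
            n_iter=config.n_iter,
            seed=config.seed,
            convention=config.params.convention,
        )

        paths: dict[str, Path] = {}
        for name, frame in tables.items():
            p = tmp / f"{name}.csv"
            frame.to_csv(p, index=False)
            paths[name] = out_dir / f"{name}.csv"

        manifest = {
            "package": "careernpv",
            "version": __version__,
            "n_specialties": len(schedule),
            "specialties": schedule.specialties,
            "source": schedule.source,
            "params": {
                "wage_growth": config.params.wage_growth,
                "discount_rate": config.params.discount_rate,
                "convention": config.params.convention,
            },
            "percentiles": list(config.percentiles),
            "variants": list(config.variants),
            "delta_percentile": config.delta_percentile,
            "mc": {
                "percentile": config.mc_percentile,
                "n_iter": config.n_iter,
                "seed": config.seed,
                "growth_spec": vars(DEFAULT_GROWTH_SPEC),
                "discount_spec": vars(DEFAULT_DISCOUNT_SPEC),
            },
            "tables": sorted(f"{n}.csv" for n in tables),
        }
        (tmp / "manifest.json").write_text(
            json.dumps(manifest, indent=2, sort_keys=True) + "\n", encoding="utf-8"
        )
        paths["manifest"] = out_dir / "manifest.json"

        out_dir.mkdir(parents=True, exist_ok=True)
        for f in tmp.iterdir():
            shutil.move(str(f), out_dir / f.name)
        return paths
    finally:
        shutil.rmtree(tmp, ignore_errors=True)
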