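"""End-to-end orchestration: simulate -> link -> census -> ratios ->
turnover -> report.

Mostly glue; every stage is also available on its own through the
individual modules.  :func:`run` returns all intermediate and final
tables in one result object and can optionally write them as tidy CSVs.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .census import SlotGrid, build_census, build_slot_grid, daily_presence_summary
from .config import SimConfig
from .descriptives import department_overview
from .ingest import LinkedDataset, link, typed_from_sheets
from .ratios import compute_ratios, compute_thresholds, department_mean_ci, key_timepoint_summary
from .synthetic import SyntheticBundle, make_bundle
from .turnover import aggregate_profiles, count_events, normalize

log = logging.getLogger("wardflow")

__all__ = ["AnalysisResult", "run", "analyse_linked"]


@dataclass
class AnalysisResult:
    bundle: SyntheticBundle | None
    linked: LinkedDataset
    grid: SlotGrid
    census: pd.DataFrame
    ratios: pd.DataFrame
    thresholds: pd.DataFrame
    key_timepoints: pd.DataFrame
    ratio_profiles: pd.DataFrame
    turnover_points: pd.DataFrame
    turnover_profiles: pd.DataFrame
    presence_summary: pd.DataFrame
    overview: pd.DataFrame

    def tables(self) -> dict[str, pd.DataFrame]:
        return {
            "funnel": self.linked.funnel.to_frame(),
            "census": self.census,
            "ratios": self.ratios,
            "thresholds": self.thresholds,
            "key_timepoints": self.key_timepoints,
            "ratio_profiles": self.ratio_profiles,
            "turnover_points": self.turnover_points,
            "turnover_profiles": self.turnover_profiles,
            "presence_summary": self.presence_summary,
            "overview": self.overview,
        }


def analyse_linked(
    linked: LinkedDataset,
    start_date,
    end_date,
    interval_minutes: int = 30,
    bundle: SyntheticBundle | None = None,
) -> AnalysisResult:
    """All analysis stages downstream of an already linked dataset."""
    units = linked.units
    grid = build_slot_grid(units, start_date, end_date, interval_minutes)
    log.info("census grid: %d units x %d days x %d slots", len(units), grid.n_days, grid.slots_per_day)
    census = build_census(linked.stays, linked.shifts, grid)

    ratios = compute_ratios(census)
    unit_dept = linked.unit_department
    thresholds = compute_thresholds(ratios)
    key_tp = key_timepoint_summary(ratios, unit_dept)
    profiles = department_mean_ci(ratios, unit_dept)

    events, excluded = count_events(linked.stays, grid)
    if len(excluded):
        log.info("turnover: %d events outside the grid span excluded", len(excluded))
    points = normalize(events, census)
    t_profiles = aggregate_profiles(points, unit_dept)

    presence = daily_presence_summary(linked.daily_presence, start_date, end_date)
    overview = department_overview(linked.cases, census, unit_dept)

    return AnalysisResult(
        bundle=bundle,
        linked=linked,
        grid=grid,
        census=census,
        ratios=ratios,
        thresholds=thresholds,
        key_timepoints=key_tp,
        ratio_profiles=profiles,
        turnover_points=points,
        turnover_profiles=t_profiles,
        presence_summary=presence,
        overview=overview,
    )


def run(config: SimConfig, interval_minutes: int = 30, outdir=None) -> AnalysisResult:
    """Simulate a bundle from ``config`` and run the full analysis."""
    log.info("simulating bundle (seed %d)", config.seed)
    bundle = make_bundle(config)
    raw = typed_from_sheets(bundle.sheets())
    log.info(
        "linking: %d activity rows, %d movement rows",
        len(raw.activity),
        len(raw.movements),
    )
    linked = link(raw, maternity_department=config.maternity_department)
    result = analyse_linked(
        linked, config.start_date, config.end_date, interval_minutes, bundle=bundle
    )
    if outdir is not None:
        write_result(result, outdir)
    return result


def write_result(result: AnalysisResult, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    for name, df in result.tables().items():
        df.to_csv(outdir / f"{name}.csv", index=False)
    log.info("wrote %d tables to %s", len(result.tables()), outdir)
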