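"""End-to-end orchestration: cohort in, cohort-level endpoints out."""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Optional

import pandas as pd

from . import (
    cohort_stats,
    event_alignment,
    period_summary,
    walk_test,
    wear_aggregation,
)
from .config import AnalysisConfig
from .types import (
    AlignedActivityCurve,
    AnalysisSetMembership,
    Cohort,
    DailyActivity,
    EmptyCurveError,
    PeriodSummary,
    WalkTestEndpoints,
)


@dataclass
class PipelineResult:
    """Everything the analysis produces for one cohort."""

    daily: dict[str, list[DailyActivity]]
    summaries: dict[str, dict[str, PeriodSummary]]
    membership: dict[str, AnalysisSetMembership]
    cohort_changes: dict[str, dict]
    curve_distance: Optional[AlignedActivityCurve]
    curve_steps: Optional[AlignedActivityCurve]
    behavior: dict[str, dict]
    walk_endpoints: dict[tuple[str, str], WalkTestEndpoints]
    change_table: pd.DataFrame
    correlations: pd.DataFrame
    wear_baseline: dict = field(default_factory=dict)
    wear_end: dict = field(default_factory=dict)


def run_pipeline(cohort: Cohort, config: Optional[AnalysisConfig] = None) -> PipelineResult:
    """Run the full analysis on an in-memory cohort.

    Event-aligned curves, behavior summaries, change table and correlations
    are restricted to the full analysis set, mirroring how such studies
    report them.
    """
    config = config or AnalysisConfig()

    daily: dict[str, list[DailyActivity]] = {}
    resting_by_patient: dict[str, dict[dt.date, Optional[float]]] = {}
    for pid in cohort.patient_ids:
        stream = cohort.streams.get(pid)
        timeline = cohort.timelines[pid]
        if stream is None:
            daily[pid] = []
            resting_by_patient[pid] = {}
            continue
        daily[pid] = wear_aggregation.aggregate_days(stream, timeline, config)
        resting_by_patient[pid] = {
            d.date: walk_test.daily_resting_hr(stream, d.date, config)
            for d in daily[pid]
            if not d.missing
        }

    membership = period_summary.full_analysis_filter(
        daily, cohort.timelines, cohort.visits, config
    )
    fas = [pid for pid in cohort.patient_ids if membership[pid].in_full_set]

    summaries: dict[str, dict[str, PeriodSummary]] = {}
    for pid in cohort.patient_ids:
        timeline = cohort.timelines[pid]
        base = period_summary.summarize_baseline(daily[pid], timeline, config)
        end = period_summary.summarize_end(daily[pid], timeline, config)
        base["resting_hr_bpm"] = period_summary.summarize_series(
            resting_by_patient[pid], timeline, config, "baseline"
        )
        end["resting_hr_bpm"] = period_summary.summarize_series(
            resting_by_patient[pid], timeline, config, "end"
        )
        summaries[pid] = period_summary.change_from_baseline(pid, base, end)

    cohort_changes = {
        measure: period_summary.cohort_change_stats(
            [summaries[pid][measure] for pid in fas if measure in summaries[pid]]
        )
        for measure in ("distance_m", "steps", "standups", "mean_hr_bpm", "resting_hr_bpm")
    }

    def _curve(measure: str) -> Optional[AlignedActivityCurve]:
        try:
            return event_alignment.cohort_curve(
                cohort.streams, cohort.sessions, config, measure, patient_ids=fas
            )
        except EmptyCurveError:
            return None

    curve_distance = _curve("distance_m")
    curve_steps = _curve("steps")

    behavior = event_alignment.cohort_behavior(
        {pid: cohort.sessions.get(pid, []) for pid in fas},
        {pid: cohort.timelines[pid] for pid in fas},
    )

    endpoints = {
        key: walk_test.walk_endpoints(trace, config) for key, trace in cohort.traces.items()
    }

    change_table = cohort_stats.build_change_table(
        summaries_to_change_columns(summaries), cohort.visits, endpoints, membership
    )
    correlations = cohort_stats.pearson_pairwise(change_table)

    wear_baseline = wear_aggregation.wear_use_table(
        {pid: _in_window(daily[pid], *period_summary.baseline_window(cohort.timelines[pid], config)) for pid in fas}
    )
    wear_end = wear_aggregation.wear_use_table(
        {pid: _in_window(daily[pid], *period_summary.end_window(cohort.timelines[pid], config)) for pid in fas}
    )

    return PipelineResult(
        daily=daily,
        summaries=summaries,
        membership=membership,
        cohort_changes=cohort_changes,
        curve_distance=curve_distance,
        curve_steps=curve_steps,
        behavior=behavior,
        walk_endpoints=endpoints,
        change_table=change_table,
        correlations=correlations,
        wear_baseline=wear_baseline,
        wear_end=wear_end,
    )


def _in_window(days: list[DailyActivity], lo: dt.date, hi: dt.date) -> list[DailyActivity]:
    return [d for d in days if lo <= d.date <= hi]


def summaries_to_change_columns(
    summaries: Mapping[str, Mapping[str, PeriodSummary]],
) -> dict[str, dict[str, PeriodSummary]]:
    """Keep the measures the change table consumes, keyed as it expects."""
    keep = ("distance_m", "steps", "standups", "resting_hr_bpm")
    return {
        pid: {m: per[m] for m in keep if m in per} for pid, per in summaries.items()
    }
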