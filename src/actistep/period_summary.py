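"""Baseline/end-of-observation summaries, changes, and analysis-set filters.

The baseline value of a daily measure is the median over the non-missing
days in the 14 calendar days strictly before the date of first inhalation;
the end value is the median over the non-missing days in the last 14
calendar days of observation. Per-patient change = end - baseline, and the
cohort-level change is summarized as the median of per-patient changes
(which is not, in general, the difference of the two cohort medians).
"""

from __future__ import annotations

import datetime as dt
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np

from .config import AnalysisConfig
from .types import (
    AnalysisSetMembership,
    DailyActivity,
    PeriodSummary,
    StudyTimeline,
    VisitRecord,
)

#: daily measures summarized by default: PeriodSummary measure name -> DailyActivity field
DAILY_MEASURES = {
    "distance_m": "norm_distance_m",
    "steps": "norm_steps",
    "standups": "norm_standups",
    "mean_hr_bpm": "mean_hr_bpm",
}


def _window_median(
    daily: Sequence[DailyActivity],
    field_name: str,
    start: dt.date,
    end: dt.date,
) -> tuple[Optional[float], int]:
    """Median of a DailyActivity field over non-missing days in [start, end]."""
    values = [
        getattr(d, field_name)
        for d in daily
        if start <= d.date <= end and not d.missing and getattr(d, field_name) is not None
    ]
    if not values:
        return None, 0
    return float(np.median(values)), len(values)


def baseline_window(timeline: StudyTimeline, config: AnalysisConfig) -> tuple[dt.date, dt.date]:
    """Calendar-day window of the baseline period (before first inhalation)."""
    treat_date = timeline.treatment_start.date()
    return treat_date - dt.timedelta(days=config.baseline_max_days), treat_date - dt.timedelta(days=1)


def end_window(timeline: StudyTimeline, config: AnalysisConfig) -> tuple[dt.date, dt.date]:
    """Last ``end_window_days`` calendar days of the observation period."""
    return (
        timeline.observation_end - dt.timedelta(days=config.end_window_days - 1),
        timeline.observation_end,
    )


def summarize_baseline(
    daily: Sequence[DailyActivity],
    timeline: StudyTimeline,
    config: AnalysisConfig,
    measures: Mapping[str, str] = DAILY_MEASURES,
) -> dict[str, tuple[Optional[float], int]]:
    """Per-measure baseline medians: {measure: (value or None, n_days)}."""
    lo, hi = baseline_window(timeline, config)
    return {m: _window_median(daily, f, lo, hi) for m, f in measures.items()}


def summarize_end(
    daily: Sequence[DailyActivity],
    timeline: StudyTimeline,
    config: AnalysisConfig,
    measures: Mapping[str, str] = DAILY_MEASURES,
) -> dict[str, tuple[Optional[float], int]]:
    """Per-measure end-of-observation medians."""
    lo, hi = end_window(timeline, config)
    return {m: _window_median(daily, f, lo, hi) for m, f in measures.items()}


def summarize_series(
    values_by_date: Mapping[dt.date, Optional[float]],
    timeline: StudyTimeline,
    config: AnalysisConfig,
    period: str,
) -> tuple[Optional[float], int]:
    """Window median of an arbitrary per-day series (e.g. daily resting HR)."""
    if period == "baseline":
        lo, hi = baseline_window(timeline, config)
    elif period == "end":
        lo, hi = end_window(timeline, config)
    else:
        raise ValueError("period must be 'baseline' or 'end'")
    vals = [v for d, v in values_by_date.items() if lo <= d <= hi and v is not None]
    if not vals:
        return None, 0
    return float(np.median(vals)), len(vals)


def change_from_baseline(
    patient_id: str,
    baseline: Mapping[str, tuple[Optional[float], int]],
    end: Mapping[str, tuple[Optional[float], int]],
) -> dict[str, PeriodSummary]:
    """Combine period medians into PeriodSummary records with change filled.

    Change is only defined for patients with both period values present.
    """
    out: dict[str, PeriodSummary] = {}
    for measure in baseline:
        b_val, b_n = baseline[measure]
        e_val, e_n = end.get(measure, (None, 0))
        change = e_val - b_val if b_val is not None and e_val is not None else None
        out[measure] = PeriodSummary(
            patient_id=patient_id,
            measure=measure,
            baseline_value=b_val,
            baseline_n_days=b_n,
            end_value=e_val,
            end_n_days=e_n,
            change=change,
        )
    return out


def cohort_change_stats(summaries: Sequence[PeriodSummary]) -> dict[str, Optional[float]]:
    """Cohort median and IQR of per-patient changes for one measure.

    Quartiles use linear interpolation (type 7), the common statistical
    software default.
    """
    changes = np.array([s.change for s in summaries if s.change is not None], dtype=float)
    if changes.size == 0:
        return {"n": 0, "median": None, "q1": None, "q3": None}
    return {
        "n": int(changes.size),
        "median": float(np.median(changes)),
        "q1": float(np.percentile(changes, 25)),
        "q3": float(np.percentile(changes, 75)),
    }


@dataclass
class SafetyInfo:
    """Safety-analysis-set flags supplied per patient."""

    received_dose: bool = True
    consent_withdrawn: bool = False
    screening_failure: bool = False


#: clinical outcomes of which at least one must be present at BOTH visits;
#: BNP and NT-proBNP each qualify on their own
_OUTCOME_FIELDS = ("six_mwd_m", "who_fc", "bnp_ng_l", "ntprobnp_ng_l")


def _has_outcome_at_both_visits(
    initial: Optional[VisitRecord], final: Optional[VisitRecord]
) -> bool:
    if initial is None or final is None:
        return False
    return any(
        getattr(initial, f) is not None and getattr(final, f) is not None
        for f in _OUTCOME_FIELDS
    )


def full_analysis_filter(
    daily_by_patient: Mapping[str, Sequence[DailyActivity]],
    timelines: Mapping[str, StudyTimeline],
    visits: Sequence[VisitRecord],
    config: AnalysisConfig,
    safety: Optional[Mapping[str, SafetyInfo]] = None,
) -> dict[str, AnalysisSetMembership]:
    """Apply the full-analysis-set rules, recording one tag per exclusion.

    A patient is in the full analysis set iff they are in the safety set
    (>=1 dose, consent not withdrawn), are not a screening failure, have at
    least ``fas_min_baseline_days`` non-missing activity days in the
    baseline window, at least ``fas_min_end_days`` in the last two weeks of
    observation, and at least one clinical outcome (6MWD, WHO FC, BNP or
    NT-proBNP) present at both visits.
    """
    safety = safety or {}
    by_visit = {(v.patient_id, v.visit): v for v in visits}
    out: dict[str, AnalysisSetMembership] = {}
    for pid, timeline in timelines.items():
        info = safety.get(pid, SafetyInfo())
        reasons: list[str] = []
        in_safety = info.received_dose and not info.consent_withdrawn
        if not info.received_dose:
            reasons.append("no_dose")
        if info.consent_withdrawn:
            reasons.append("consent_withdrawn")
        if info.screening_failure:
            reasons.append("screening_failure")
        daily = daily_by_patient.get(pid, ())
        lo, hi = baseline_window(timeline, config)
        n_base = sum(1 for d in daily if lo <= d.date <= hi and not d.missing)
        if n_base < config.fas_min_baseline_days:
            reasons.append("baseline_activity")
        lo, hi = end_window(timeline, config)
        n_end = sum(1 for d in daily if lo <= d.date <= hi and not d.missing)
        if n_end < config.fas_min_end_days:
            reasons.append("end_activity")
        if not _has_outcome_at_both_visits(
            by_visit.get((pid, "initial")), by_visit.get((pid, "final"))
        ):
            reasons.append("clinical_outcome")
        out[pid] = AnalysisSetMembership(
            patient_id=pid,
            in_safety_set=in_safety,
            in_full_set=in_safety and not reasons,
            exclusion_reasons=reasons,
        )
    return out
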