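"""Event-aligned post-inhalation activity curves and inhalation summaries.

For every inhalation session, 12 consecutive 15-minute bins start at the end
of the session (rounded up to the next whole minute to match the epoch
grid). A bin's value is the summed activity over its worn minutes. A session
is excluded when any minute of bins 2-12 is unworn; the first bin may be
partially worn (its raw, unscaled sum is used), reconciling the all-or-
nothing exclusion rule with partially covered first intervals. Strict mode
(``config.strict_alignment``) excludes on any unworn minute anywhere.
Overlapping 3-hour windows from nearby sessions each contribute
independently; complete and incomplete inhalations both enter.

Averaging is three-level: bin-wise over a patient-day's included sessions,
then bin-wise over all patient-day vectors to give the cohort curve.
"""

from __future__ import annotations

import datetime as dt
import math
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .types import (
    AlignedActivityCurve,
    EmptyCurveError,
    InhalationSession,
    SampleStream,
    SessionCurve,
    StudyTimeline,
)


def _ceil_minute(t: dt.datetime) -> dt.datetime:
    if t.second == 0 and t.microsecond == 0:
        return t
    return (t + dt.timedelta(minutes=1)).replace(second=0, microsecond=0)


def _dense_minutes(stream: SampleStream, measure: str) -> tuple[Optional[pd.Timestamp], np.ndarray, np.ndarray]:
    """Dense minute grid over stream coverage: (t0, values, worn mask)."""
    df = stream.epochs
    if df.empty:
        return None, np.empty(0), np.empty(0, dtype=bool)
    t0 = df.index[0]
    offsets = ((df.index - t0).total_seconds() // 60).astype(int)
    n = int(offsets[-1]) + 1
    values = np.zeros(n)
    worn = np.zeros(n, dtype=bool)
    present_hr = df["heart_rate_bpm"].notna().to_numpy()
    worn[offsets] = present_hr
    vals = df[measure].to_numpy(dtype=float)
    values[offsets] = np.where(present_hr, vals, 0.0)
    return t0, values, worn


def align_sessions(
    stream: SampleStream,
    sessions: Sequence[InhalationSession],
    config: AnalysisConfig,
    measure: str = "distance_m",
) -> list[SessionCurve]:
    """Bin each session's post-inhalation activity and flag inclusion."""
    n_bins, bin_min = config.n_bins, config.bin_minutes
    horizon = n_bins * bin_min
    t0, values, worn = _dense_minutes(stream, measure)
    curves: list[SessionCurve] = []
    for session in sessions:
        end_min = _ceil_minute(session.end)
        if t0 is None:
            curves.append(
                SessionCurve(stream.patient_id, session, np.zeros(n_bins), False, "beyond_coverage", False)
            )
            continue
        start_idx = int((pd.Timestamp(end_min) - t0).total_seconds() // 60)
        idx = start_idx + np.arange(horizon)
        in_range = (idx >= 0) & (idx < len(values))
        w = np.zeros(horizon, dtype=bool)
        v = np.zeros(horizon)
        w[in_range] = worn[idx[in_range]]
        v[in_range] = values[idx[in_range]]
        w_bins = w.reshape(n_bins, bin_min)
        bins = np.where(w_bins, v.reshape(n_bins, bin_min), 0.0).sum(axis=1)
        followup_worn = w_bins[1:].all() if not config.strict_alignment else w_bins.all()
        if followup_worn:
            curves.append(
                SessionCurve(
                    stream.patient_id,
                    session,
                    bins,
                    True,
                    None,
                    partial_first_bin=not w_bins[0].all(),
                )
            )
        else:
            beyond = start_idx + horizon > len(values)
            reason = "beyond_coverage" if beyond else "unworn_followup"
            curves.append(SessionCurve(stream.patient_id, session, bins, False, reason, False))
    return curves


def average_curves(
    curves: Sequence[SessionCurve], measure: str = "distance_m", bin_minutes: int = 15
) -> AlignedActivityCurve:
    """Three-level average of included session curves into a cohort profile."""
    included = [c for c in curves if c.included]
    if not included:
        raise EmptyCurveError("no included inhalation sessions to average")
    n_bins = len(included[0].bins)
    by_patient_day: dict[tuple[str, dt.date], list[np.ndarray]] = {}
    for c in included:
        by_patient_day.setdefault((c.patient_id, c.day), []).append(c.bins)
    per_patient_day = {
        key: np.mean(np.vstack(vecs), axis=0) for key, vecs in by_patient_day.items()
    }
    cohort = np.mean(np.vstack(list(per_patient_day.values())), axis=0)
    return AlignedActivityCurve(
        measure=measure,
        n_bins=n_bins,
        bin_minutes=bin_minutes,
        cohort_means=cohort,
        per_patient_day_curves=per_patient_day,
        included_inhalations=len(included),
        excluded_inhalations=len(curves) - len(included),
        partial_first_bin_count=sum(1 for c in included if c.partial_first_bin),
    )


def cohort_curve(
    streams: Mapping[str, SampleStream],
    sessions: Mapping[str, Sequence[InhalationSession]],
    config: AnalysisConfig,
    measure: str = "distance_m",
    patient_ids: Optional[Sequence[str]] = None,
) -> AlignedActivityCurve:
    """Align and average sessions across a cohort in one call."""
    pids = list(patient_ids) if patient_ids is not None else sorted(streams)
    all_curves: list[SessionCurve] = []
    for pid in pids:
        if pid in streams and pid in sessions:
            all_curves.extend(align_sessions(streams[pid], sessions[pid], config, measure))
    return average_curves(all_curves, measure, bin_minutes=config.bin_minutes)


def inhalation_behavior(
    sessions: Sequence[InhalationSession], timeline: StudyTimeline
) -> Optional[dict[str, float]]:
    """Per-patient inhalation-behavior summary over the observation period.

    Daily session counts are tallied over every calendar day from treatment
    start through observation end (days without sessions count 0); duration
    and completeness are summarized over days with at least one session.
    Sessions are attributed to the calendar date of their end time.
    """
    if not sessions:
        return None
    start = timeline.treatment_start.date()
    end = timeline.observation_end
    n_days = (end - start).days + 1
    by_day: dict[dt.date, list[InhalationSession]] = {}
    for s in sessions:
        d = s.end.date()
        if start <= d <= end:
            by_day.setdefault(d, []).append(s)
    counts = np.zeros(n_days)
    for d, group in by_day.items():
        counts[(d - start).days] = len(group)
    daily_duration = [float(np.mean([s.duration_min for s in g])) for g in by_day.values()]
    daily_pct_complete = [
        100.0 * np.mean([s.complete for s in g]) for g in by_day.values()
    ]
    return {
        "patient_id_days": float(n_days),
        "median_daily_sessions": float(np.median(counts)),
        "mean_daily_sessions": float(np.mean(counts)),
        "median_daily_duration_min": float(np.median(daily_duration)) if daily_duration else math.nan,
        "median_daily_pct_complete": float(np.median(daily_pct_complete)) if daily_pct_complete else math.nan,
    }


def cohort_behavior(
    sessions_by_patient: Mapping[str, Sequence[InhalationSession]],
    timelines: Mapping[str, StudyTimeline],
) -> dict[str, dict[str, float]]:
    """Cohort medians (with IQR) of the per-patient behavior summaries."""
    per_patient = {}
    for pid, timeline in timelines.items():
        summary = inhalation_behavior(sessions_by_patient.get(pid, ()), timeline)
        if summary is not None:
            per_patient[pid] = summary
    out: dict[str, dict[str, float]] = {}
    for key in ("median_daily_sessions", "median_daily_duration_min", "median_daily_pct_complete"):
        vals = np.array([s[key] for s in per_patient.values() if not math.isnan(s[key])])
        out[key] = {
            "n": int(vals.size),
            "median": float(np.median(vals)) if vals.size else math.nan,
            "q1": float(np.percentile(vals, 25)) if vals.size else math.nan,
            "q3": float(np.percentile(vals, 75)) if vals.size else math.nan,
        }
    return out
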