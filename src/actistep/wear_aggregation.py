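"""Wear-time detection and wear-normalized daily activity totals.

A minute counts as worn iff an epoch exists for it AND the epoch carries a
heart-rate sample: optical heart rate requires skin contact, whereas step
counters can register off-wrist motion. Daily totals are taken over worn
minutes inside the activity window (default 6 AM to midnight, 18 h) and
scaled up to the full window by dividing by the wear fraction. A day worn
for less than ``min_wear_fraction`` (default 10%) of the window is treated
as missing and gets no normalized values. Heart rate is an intensity, not a
count, so it is averaged over worn minutes and never scaled.
"""

from __future__ import annotations

import datetime as dt
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .config import AnalysisConfig
from .types import DailyActivity, SampleStream, StudyTimeline


def _window_slice(stream: SampleStream, date: dt.date, config: AnalysisConfig) -> pd.DataFrame:
    """Epochs of ``date`` falling inside the activity window."""
    start = pd.Timestamp(date) + pd.Timedelta(hours=config.activity_window_start_hour)
    end = pd.Timestamp(date) + pd.Timedelta(hours=config.activity_window_end_hour)
    df = stream.epochs
    lo = df.index.searchsorted(start, side="left")
    hi = df.index.searchsorted(end, side="left")
    return df.iloc[lo:hi]


def detect_wear_minutes(stream: SampleStream, date: dt.date, config: AnalysisConfig) -> int:
    """Count worn minutes of ``date`` within the activity window.

    A date outside the stream's coverage simply yields 0.
    """
    day = _window_slice(stream, date, config)
    return int(day["heart_rate_bpm"].notna().sum())


def aggregate_day(stream: SampleStream, date: dt.date, config: AnalysisConfig) -> DailyActivity:
    """Aggregate one patient-day into raw and wear-normalized totals."""
    day = _window_slice(stream, date, config)
    worn = day[day["heart_rate_bpm"].notna()]
    wear_minutes = len(worn)
    window_minutes = config.window_minutes
    wear_fraction = wear_minutes / window_minutes
    raw_distance = float(worn["distance_m"].sum())
    raw_steps = float(worn["steps"].sum())
    raw_standups = float(worn["standup_events"].sum())
    mean_hr = float(worn["heart_rate_bpm"].mean()) if wear_minutes else None
    missing = wear_fraction < config.min_wear_fraction
    if missing:
        norm = (None, None, None)
    else:
        norm = (
            raw_distance / wear_fraction,
            raw_steps / wear_fraction,
            raw_standups / wear_fraction,
        )
    return DailyActivity(
        patient_id=stream.patient_id,
        date=date,
        window_minutes=window_minutes,
        wear_minutes=wear_minutes,
        raw_distance_m=raw_distance,
        raw_steps=raw_steps,
        raw_standups=raw_standups,
        mean_hr_bpm=mean_hr,
        missing=missing,
        norm_distance_m=norm[0],
        norm_steps=norm[1],
        norm_standups=norm[2],
    )


def aggregate_days(
    stream: SampleStream, timeline: StudyTimeline, config: AnalysisConfig
) -> list[DailyActivity]:
    """Aggregate every calendar day from enrollment through observation end."""
    days: list[DailyActivity] = []
    date = timeline.enrollment_date
    while date <= timeline.observation_end:
        days.append(aggregate_day(stream, date, config))
        date += dt.timedelta(days=1)
    return days


_DAY_CATEGORIES = ("<7", ">=7", ">=10", "14")
_HOUR_CATEGORIES = ("<6", ">=6", ">=10", ">=14", "18")


def wear_use_table(
    daily_by_patient: Mapping[str, Sequence[DailyActivity]],
) -> dict[str, dict[str, int]]:
    """Tabulate smartwatch use per patient over a period.

    Categories mirror the conventional study-report layout: number of days
    worn (<7 / >=7 / >=10 / 14) and average daily hours worn over worn days
    (<6 / >=6 / >=10 / >=14 / 18). A day counts as worn iff it is not
    missing; the ">="-categories are cumulative, so one patient can appear
    in several.
    """
    days_worn = {c: 0 for c in _DAY_CATEGORIES}
    avg_hours = {c: 0 for c in _HOUR_CATEGORIES}
    for daily in daily_by_patient.values():
        worn_days = [d for d in daily if not d.missing]
        n = len(worn_days)
        if n < 7:
            days_worn["<7"] += 1
        if n >= 7:
            days_worn[">=7"] += 1
        if n >= 10:
            days_worn[">=10"] += 1
        if n >= 14:
            days_worn["14"] += 1
        if not worn_days:
            avg_hours["<6"] += 1
            continue
        hours = float(np.mean([d.wear_minutes for d in worn_days])) / 60.0
        if hours < 6:
            avg_hours["<6"] += 1
        if hours >= 6:
            avg_hours[">=6"] += 1
        if hours >= 10:
            avg_hours[">=10"] += 1
        if hours >= 14:
            avg_hours[">=14"] += 1
        if hours >= 18:
            avg_hours["18"] += 1
    return {"days_worn": days_worn, "avg_hours_worn": avg_hours}


def daily_to_frame(daily: Sequence[DailyActivity]) -> pd.DataFrame:
    """Flatten DailyActivity records into a DataFrame (one row per day)."""
    rows = []
    for d in daily:
        rows.append(
            {
                "patient_id": d.patient_id,
                "date": d.date.isoformat(),
                "window_minutes": d.window_minutes,
                "wear_minutes": d.wear_minutes,
                "wear_fraction": d.wear_fraction,
                "raw_distance_m": d.raw_distance_m,
                "raw_steps": d.raw_steps,
                "raw_standups": d.raw_standups,
                "mean_hr_bpm": d.mean_hr_bpm,
                "missing": d.missing,
                "norm_distance_m": d.norm_distance_m,
                "norm_steps": d.norm_steps,
                "norm_standups": d.norm_standups,
            }
        )
    return pd.DataFrame(rows)
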