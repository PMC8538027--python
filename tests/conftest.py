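"""Shared builders for compact test fixtures."""

from __future__ import annotations

import datetime as dt

import numpy as np
import pandas as pd
import pytest

from actistep.config import AnalysisConfig
from actistep.types import DailyActivity, SampleStream, StudyTimeline


@pytest.fixture
def config() -> AnalysisConfig:
    return AnalysisConfig()


def make_stream(
    patient_id: str,
    start: str,
    n_minutes: int,
    steps=5,
    distance_m=None,
    standups=0,
    hr=80.0,
) -> SampleStream:
    """Contiguous minute epochs from ``start``; scalars broadcast.

    ``hr`` may contain NaN to mark unworn minutes; ``distance_m`` defaults
    to 0.7 m per step.
    """
    idx = pd.date_range(start, periods=n_minutes, freq="min")
    steps = np.broadcast_to(np.asarray(steps), (n_minutes,)).astype(int)
    if distance_m is None:
        distance_m = steps * 0.7
    distance_m = np.broadcast_to(np.asarray(distance_m, dtype=float), (n_minutes,))
    standups = np.broadcast_to(np.asarray(standups), (n_minutes,)).astype(int)
    hr = np.broadcast_to(np.asarray(hr, dtype=float), (n_minutes,))
    return SampleStream(
        patient_id=patient_id,
        epochs=pd.DataFrame(
            {
                "steps": steps,
                "distance_m": distance_m,
                "standup_events": standups,
                "heart_rate_bpm": hr,
            },
            index=idx,
        ),
    )


def make_timeline(
    patient_id: str = "P1",
    enrollment: str = "2023-01-02",
    treatment_start: str = "2023-01-10T08:00",
    observation_end: str = "2023-04-10",
) -> StudyTimeline:
    return StudyTimeline(
        patient_id=patient_id,
        enrollment_date=dt.date.fromisoformat(enrollment),
        treatment_start=dt.datetime.fromisoformat(treatment_start),
        observation_end=dt.date.fromisoformat(observation_end),
    )


def make_day(
    patient_id: str,
    date: str | dt.date,
    norm_steps: float | None = None,
    missing: bool = False,
    wear_minutes: int = 540,
    **overrides,
) -> DailyActivity:
    """DailyActivity with internally consistent defaults for summary tests."""
    if isinstance(date, str):
        date = dt.date.fromisoformat(date)
    window = 1080
    frac = wear_minutes / window
    if missing:
        norm = dict(norm_distance_m=None, norm_steps=None, norm_standups=None)
    else:
        ns = norm_steps if norm_steps is not None else 8000.0
        norm = dict(norm_distance_m=ns * 0.7, norm_steps=ns, norm_standups=24.0)
    fields = dict(
        patient_id=patient_id,
        date=date,
        window_minutes=window,
        wear_minutes=wear_minutes,
        raw_distance_m=(norm["norm_distance_m"] or 0.0) * frac,
        raw_steps=(norm["norm_steps"] or 0.0) * frac,
        raw_standups=(norm["norm_standups"] or 0.0) * frac,
        mean_hr_bpm=None if missing else 78.0,
        missing=missing,
        **norm,
    )
    fields.update(overrides)
    return DailyActivity(**fields)
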