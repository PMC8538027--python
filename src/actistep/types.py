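"""Domain types for smartwatch activity streams, inhalation logs and visits.

All epoch data live on a one-minute grid in local clinic time (naive
timestamps, no DST arithmetic); a "day" is a calendar day on that clock.
Sub-minute device exports must be pre-binned by the caller.
"""

from __future__ import annotations

import datetime as dt
import warnings
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd


class ValidationError(ValueError):
    """An input violates a domain invariant."""


class ParseError(ValueError):
    """A file could not be parsed; the message names the offending row."""


class EmptyCurveError(ValidationError):
    """No included inhalation sessions were available for averaging."""


EPOCH_COLUMNS = ("steps", "distance_m", "standup_events", "heart_rate_bpm")

#: plausible human heart-rate band; samples outside are rejected, not clipped
HR_MIN_BPM = 20.0
HR_MAX_BPM = 250.0

VISITS = ("initial", "final")
WHO_CLASSES = ("I", "II", "III", "IV")


@dataclass
class SampleStream:
    """Per-patient minute-resolution sensor epochs.

    ``epochs`` is indexed by a strictly increasing minute-resolution
    DatetimeIndex with columns ``steps`` (count), ``distance_m`` (meters),
    ``standup_events`` (count) and ``heart_rate_bpm`` (bpm, NaN = absent).
    A minute with no row means the watch recorded nothing in that minute.
    """

    patient_id: str
    epochs: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.epochs
        if not isinstance(df.index, pd.DatetimeIndex):
            raise ValidationError("epochs must be indexed by timestamps")
        missing = [c for c in EPOCH_COLUMNS if c not in df.columns]
        if missing:
            raise ValidationError(f"epochs missing columns {missing}")
        idx = df.index
        if len(idx) and ((idx.second != 0).any() or (idx.microsecond != 0).any()):
            raise ValidationError("epoch timestamps must lie on whole minutes")
        if idx.has_duplicates:
            dup = idx[idx.duplicated()][0]
            raise ValidationError(f"duplicate epoch minute {dup}")
        if not idx.is_monotonic_increasing:
            raise ValidationError("epoch timestamps must be strictly increasing")
        for col in ("steps", "distance_m", "standup_events"):
            vals = df[col].to_numpy()
            if np.isnan(vals).any():
                raise ValidationError(f"{col} contains missing values")
            if (vals < 0).any():
                raise ValidationError(f"{col} contains negative values")
        for col in ("steps", "standup_events"):
            vals = df[col].to_numpy(dtype=float)
            if not np.array_equal(vals, np.floor(vals)):
                raise ValidationError(f"{col} must be integer counts")
        hr = df["heart_rate_bpm"].to_numpy(dtype=float)
        present = ~np.isnan(hr)
        if ((hr[present] <= HR_MIN_BPM) | (hr[present] >= HR_MAX_BPM)).any():
            raise ValidationError(
                f"heart_rate_bpm outside ({HR_MIN_BPM}, {HR_MAX_BPM})"
            )

    def __len__(self) -> int:
        return len(self.epochs)

    @property
    def start(self) -> Optional[pd.Timestamp]:
        return self.epochs.index[0] if len(self.epochs) else None

    @property
    def end(self) -> Optional[pd.Timestamp]:
        return self.epochs.index[-1] if len(self.epochs) else None


@dataclass(frozen=True)
class InhalationSession:
    """One nebulizer session: start/end, completeness flag and dose."""

    patient_id: str
    start: dt.datetime
    end: dt.datetime
    complete: bool
    dose_ug: float

    def __post_init__(self) -> None:
        if self.end <= self.start:
            raise ValidationError(
                f"session end {self.end} not after start {self.start}"
            )
        if self.duration_min > 60.0:
            raise ValidationError(f"session longer than 60 min: {self.duration_min:.1f}")
        if not self.dose_ug > 0:
            raise ValidationError("dose_ug must be positive")

    @property
    def duration_min(self) -> float:
        return (self.end - self.start).total_seconds() / 60.0


@dataclass(frozen=True)
class VisitRecord:
    """Traditional clinical measures and PRO scores at one visit.

    Absent cells stay ``None``; nothing is imputed at the I/O layer.
    """

    patient_id: str
    visit: str
    six_mwd_m: Optional[float] = None
    borg: Optional[float] = None
    who_fc: Optional[str] = None
    bnp_ng_l: Optional[float] = None
    ntprobnp_ng_l: Optional[float] = None
    eq5d_index: Optional[float] = None
    psqi_global: Optional[int] = None

    def __post_init__(self) -> None:
        if self.visit not in VISITS:
            raise ValidationError(f"visit must be one of {VISITS}, got {self.visit!r}")
        if self.six_mwd_m is not None and self.six_mwd_m < 0:
            raise ValidationError("six_mwd_m must be nonnegative")
        if self.borg is not None and not (0.0 <= self.borg <= 10.0):
            raise ValidationError(f"borg {self.borg} outside [0, 10]")
        if self.who_fc is not None and self.who_fc not in WHO_CLASSES:
            raise ValidationError(f"who_fc must be one of {WHO_CLASSES}")
        for name in ("bnp_ng_l", "ntprobnp_ng_l"):
            v = getattr(self, name)
            if v is not None and v < 0:
                raise ValidationError(f"{name} must be nonnegative")
        if self.eq5d_index is not None and not (-0.6 <= self.eq5d_index <= 1.0):
            raise ValidationError("eq5d_index outside [-0.6, 1.0]")
        if self.psqi_global is not None and not (0 <= self.psqi_global <= 21):
            raise ValidationError("psqi_global outside [0, 21]")
        if self.bnp_ng_l is not None and self.ntprobnp_ng_l is not None:
            warnings.warn(
                f"patient {self.patient_id}: both BNP and NT-proBNP present; "
                "sites usually measure one",
                stacklevel=2,
            )


@dataclass(frozen=True)
class StudyTimeline:
    """Enrollment, first inhalation (treatment start) and observation end."""

    patient_id: str
    enrollment_date: dt.date
    treatment_start: dt.datetime
    observation_end: dt.date

    def __post_init__(self) -> None:
        if self.treatment_start.date() < self.enrollment_date:
            raise ValidationError("treatment_start before enrollment_date")
        if self.observation_end <= self.treatment_start.date():
            raise ValidationError("observation_end not after treatment start date")


@dataclass
class DailyActivity:
    """One patient-day of wear-time accounting and (normalized) totals.

    ``norm_*`` values scale raw totals to the full 18-h activity window
    (raw / wear_fraction); they are absent when the day is missing
    (wear fraction below the configured minimum).
    """

    patient_id: str
    date: dt.date
    window_minutes: int
    wear_minutes: int
    raw_distance_m: float
    raw_steps: float
    raw_standups: float
    mean_hr_bpm: Optional[float]
    missing: bool
    norm_distance_m: Optional[float]
    norm_steps: Optional[float]
    norm_standups: Optional[float]

    @property
    def wear_fraction(self) -> float:
        return self.wear_minutes / self.window_minutes


@dataclass
class PeriodSummary:
    """Baseline/end medians and change for one patient and measure."""

    patient_id: str
    measure: str
    baseline_value: Optional[float]
    baseline_n_days: int
    end_value: Optional[float]
    end_n_days: int
    change: Optional[float] = None


@dataclass
class AnalysisSetMembership:
    patient_id: str
    in_safety_set: bool
    in_full_set: bool
    exclusion_reasons: list[str] = field(default_factory=list)


@dataclass
class SessionCurve:
    """Bin vector for one inhalation session, with inclusion accounting."""

    patient_id: str
    session: InhalationSession
    bins: np.ndarray
    included: bool
    reason: Optional[str]
    partial_first_bin: bool

    @property
    def day(self) -> dt.date:
        # sessions are attributed to the calendar date of their end time
        return self.session.end.date()


@dataclass
class AlignedActivityCurve:
    """Cohort-level post-inhalation activity profile (12 x 15-min bins)."""

    measure: str
    n_bins: int
    bin_minutes: int
    cohort_means: np.ndarray
    per_patient_day_curves: dict[tuple[str, dt.date], np.ndarray]
    included_inhalations: int
    excluded_inhalations: int
    partial_first_bin_count: int


@dataclass
class WalkTestTrace:
    """Per-minute smartwatch record around one 6-minute walk test.

    ``pre_hr``/``pre_steps`` cover the minutes immediately before the test
    (last element = minute -1), ``in_hr`` the six test minutes, ``post_hr``
    the recovery minutes after test end.
    """

    patient_id: str
    visit: str
    test_start: dt.datetime
    pre_hr: np.ndarray
    pre_steps: np.ndarray
    in_hr: np.ndarray
    post_hr: np.ndarray
    steps_in_test: int
    traditional_distance_m: Optional[float] = None

    def __post_init__(self) -> None:
        self.pre_hr = np.asarray(self.pre_hr, dtype=float)
        self.pre_steps = np.asarray(self.pre_steps, dtype=float)
        self.in_hr = np.asarray(self.in_hr, dtype=float)
        self.post_hr = np.asarray(self.post_hr, dtype=float)
        if self.visit not in VISITS:
            raise ValidationError(f"visit must be one of {VISITS}")
        if self.in_hr.shape != (6,):
            raise ValidationError("in_hr must hold exactly 6 per-minute samples")
        if len(self.pre_hr) != len(self.pre_steps):
            raise ValidationError("pre_hr and pre_steps must align")
        for arr in (self.pre_hr, self.in_hr, self.post_hr):
            vals = arr[~np.isnan(arr)]
            if ((vals <= HR_MIN_BPM) | (vals >= HR_MAX_BPM)).any():
                raise ValidationError("trace HR outside plausible band")
        if self.steps_in_test < 0:
            raise ValidationError("steps_in_test must be nonnegative")

    @property
    def test_end(self) -> dt.datetime:
        return self.test_start + dt.timedelta(minutes=6)


@dataclass
class WalkTestEndpoints:
    """Digital endpoints derived from one walk-test trace.

    Recovery-curve sign convention: negative values mean the heart rate is
    dropping below its end-of-test level (i.e. recovering).
    """

    patient_id: str
    visit: str
    digital_6mwd_m: Optional[float]
    resting_hr_bpm: Optional[float]
    per_minute_hr_change: Optional[np.ndarray]
    chronotropic_response_bpm: Optional[float]
    recovery_offsets_min: np.ndarray
    recovery_curve: np.ndarray


@dataclass
class Cohort:
    """In-memory cohort: streams, inhalation logs, timelines, visits, traces."""

    streams: dict[str, SampleStream]
    sessions: dict[str, list[InhalationSession]]
    timelines: dict[str, StudyTimeline]
    visits: list[VisitRecord]
    traces: dict[tuple[str, str], WalkTestTrace] = field(default_factory=dict)

    @property
    def patient_ids(self) -> list[str]:
        return sorted(self.timelines)

    def visit(self, patient_id: str, visit: str) -> Optional[VisitRecord]:
        for rec in self.visits:
            if rec.patient_id == patient_id and rec.visit == visit:
                return rec
        return None
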