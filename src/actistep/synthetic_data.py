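"""Synthetic smartwatch cohort generator with known ground truth.

Emulates the data streams of a ~3-month observational cohort on inhaled
therapy: per-patient minute-resolution sensor epochs (steps, distance,
standing-up events, heart rate) during intermittent daytime wear, nebulizer
session logs (~5 sessions/day of ~5.5 min, mostly complete), study
timelines, and initial/final visit records with walk-test traces.

Generative model, per patient:

* wear: random daily blocks inside the 6 AM-midnight window totalling the
  patient's wear-hours draw (uniform on 4.8-11.5 h/day by default);
* activity: circadian-modulated (two-peak) Poisson step counts whose daily
  expectation matches the patient's latent daily distance; distance =
  steps x latent stride;
* treatment effect: the latent daily distance ramps up linearly from
  treatment start, reaching the patient's effect (default +0.4 km) at the
  end of observation;
* post-inhalation boost: a multiplicative boost 1 + A*exp(-dt/tau) on the
  step rate, with dt the minutes since the END of the most recent session
  (a new dose refreshes, rather than stacks on, the previous one);
* heart rate: resting level + slope x step rate + noise, present only on
  worn minutes (wear detection downstream keys on HR presence);
* visits: traditional 6MWD tied to the latent stride and a walk-test step
  count that shifts with the patient's realized treatment effect, so
  change-score correlations between traditional and digital endpoints
  arise mechanistically; heart-rate recovery is slower at the final visit.

All randomness flows from one seed through per-patient ``SeedSequence``
spawns, so regeneration under the same parameters is byte-identical.
``GroundTruth`` stores the latent parameters and the noiseless expected
daily distance per day (full-wear basis, including ramp and boost) for
recovery tests.
"""

from __future__ import annotations

import dataclasses
import datetime as dt
import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .sensor_io import write_cohort
from .types import (
    Cohort,
    InhalationSession,
    SampleStream,
    StudyTimeline,
    ValidationError,
    VisitRecord,
    WalkTestTrace,
)

_WINDOW_START_MIN = 6 * 60
_WINDOW_MIN = 18 * 60  # worn-data window emulated by the generator


@dataclass
class CohortParams:
    """Generator settings; defaults encode the emulated study conditions.

    Cohort-scale defaults follow the printed cohort summaries: 18 patients,
    ~91-day observation after a 4-14 day baseline, 5.0 inhalation sessions
    per day of 5.5 minutes (90% complete, 2.5 ug), wear between 4.8 and
    11.5 hours per day, median daily distance ~5.2 km, resting heart rate
    ~76 bpm, a +0.4 km gradual treatment effect and a +20% post-inhalation
    activity boost decaying over ~60 minutes.
    """

    n_patients: int = 18
    start_date: dt.date = dt.date(2023, 1, 2)
    baseline_days_min: int = 4
    baseline_days_max: int = 14
    observation_days: int = 91
    sessions_per_day_mean: float = 5.0
    #: fixed daily clock times ("HH:MM") overriding Poisson scheduling
    session_times: Optional[tuple[str, ...]] = None
    session_duration_mean_min: float = 5.5
    session_duration_sd_min: float = 1.5
    p_complete: float = 0.9
    dose_ug: float = 2.5
    wear_hours_min: float = 4.8
    wear_hours_max: float = 11.5
    full_wear: bool = False
    daily_distance_km_mean: float = 5.2
    daily_distance_km_sd: float = 2.0
    day_noise_cv: float = 0.15
    treatment_effect_km: float = 0.4
    effect_sd_frac: float = 0.5
    boost_amplitude: float = 0.2
    boost_decay_min: float = 60.0
    circadian: bool = True
    stride_m_mean: float = 0.70
    stride_m_sd: float = 0.06
    standups_per_day_mean: float = 24.0
    hr_rest_mean: float = 76.0
    hr_rest_sd: float = 8.0
    hr_activity_slope: float = 0.25
    hr_noise_sd: float = 3.0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        if self.n_patients <= 0 or self.observation_days <= 0:
            raise ValidationError("n_patients and observation_days must be positive")
        if not (0 < self.baseline_days_min <= self.baseline_days_max):
            raise ValidationError("baseline day range must be positive and ordered")
        if not (0.0 <= self.p_complete <= 1.0):
            raise ValidationError("p_complete must lie in [0, 1]")
        for name in (
            "sessions_per_day_mean",
            "session_duration_mean_min",
            "dose_ug",
            "daily_distance_km_mean",
            "boost_decay_min",
            "stride_m_mean",
            "hr_rest_mean",
        ):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not (0 < self.wear_hours_min <= self.wear_hours_max <= 18):
            raise ValidationError("wear hours must satisfy 0 < min <= max <= 18")
        if self.boost_amplitude < 0:
            raise ValidationError("boost_amplitude must be nonnegative")


@dataclass
class PatientTruth:
    """Latent per-patient parameters plus noiseless expected daily distance."""

    patient_id: str
    stride_m: float
    hr_rest_bpm: float
    base_daily_km: float
    effect_km: float
    wear_hours: float
    first_date: dt.date
    expected_daily_km: np.ndarray  # one value per calendar day from first_date


@dataclass
class GroundTruth:
    params: CohortParams
    patients: dict[str, PatientTruth] = field(default_factory=dict)

    def to_json(self, path: str | Path) -> None:
        data = {
            "params": {
                k: (v.isoformat() if isinstance(v, dt.date) else list(v) if isinstance(v, tuple) else v)
                for k, v in dataclasses.asdict(self.params).items()
            },
            "patients": {
                pid: {
                    "stride_m": t.stride_m,
                    "hr_rest_bpm": t.hr_rest_bpm,
                    "base_daily_km": t.base_daily_km,
                    "effect_km": t.effect_km,
                    "wear_hours": t.wear_hours,
                    "first_date": t.first_date.isoformat(),
                    "expected_daily_km": [round(float(x), 9) for x in t.expected_daily_km],
                }
                for pid, t in self.patients.items()
            },
        }
        Path(path).write_text(json.dumps(data, indent=1, sort_keys=True) + "\n")


def _two_peak_circadian(window_min: int = _WINDOW_MIN) -> np.ndarray:
    """Fixed morning/afternoon activity weight profile with mean 1."""
    m = np.arange(window_min, dtype=float)  # minutes since 6 AM
    peak1 = np.exp(-0.5 * ((m - 4 * 60) / 110.0) ** 2)  # ~10 AM
    peak2 = 0.85 * np.exp(-0.5 * ((m - 10 * 60) / 150.0) ** 2)  # ~4 PM
    w = 0.30 + peak1 + peak2
    return w / w.mean()


def _wear_mask(rng: np.random.Generator, target_minutes: int, window_min: int) -> np.ndarray:
    """Random contiguous wear blocks totalling ``target_minutes``."""
    target = int(np.clip(target_minutes, 1, window_min))
    if target >= window_min:
        return np.ones(window_min, dtype=bool)
    k = int(rng.integers(2, 5))
    k = min(k, target)
    lens = rng.multinomial(target - k, [1.0 / k] * k) + 1
    gaps = rng.multinomial(window_min - target, [1.0 / (k + 1)] * (k + 1))
    mask = np.zeros(window_min, dtype=bool)
    pos = 0
    for i in range(k):
        pos += gaps[i]
        mask[pos : pos + lens[i]] = True
        pos += lens[i]
    # uniform random rotation makes per-minute coverage probability flat, so
    # wear-normalized totals stay unbiased under the circadian profile
    return np.roll(mask, int(rng.integers(0, window_min)))


def _daily_sessions(
    rng: np.random.Generator,
    pid: str,
    date: dt.date,
    params: CohortParams,
) -> list[InhalationSession]:
    if params.session_times is not None:
        starts = []
        for hhmm in params.session_times:
            h, m = hhmm.split(":")
            starts.append(int(h) * 60 + int(m))
        starts = np.array(sorted(starts))
    else:
        grid = np.arange(7 * 60, 22 * 60, 20)
        n = min(int(rng.poisson(params.sessions_per_day_mean)), len(grid))
        if n == 0:
            return []
        starts = np.sort(rng.choice(grid, size=n, replace=False) + rng.integers(0, 5, n))
    sessions = []
    for m in starts:
        dur = float(np.clip(rng.normal(params.session_duration_mean_min, params.session_duration_sd_min), 1.5, 14.0))
        start = dt.datetime.combine(date, dt.time(int(m) // 60, int(m) % 60))
        end = start + dt.timedelta(seconds=round(dur * 60))
        sessions.append(
            InhalationSession(
                patient_id=pid,
                start=start,
                end=end,
                complete=bool(rng.random() < params.p_complete),
                dose_ug=params.dose_ug,
            )
        )
    return sessions


def _ceil_abs_minute(t: dt.datetime, origin: dt.date) -> int:
    base = dt.datetime.combine(origin, dt.time())
    mins = (t - base).total_seconds() / 60.0
    return int(math.ceil(mins - 1e-9))


def _generate_patient(
    pid: str, seq: np.random.SeedSequence, params: CohortParams
) -> tuple[SampleStream, list[InhalationSession], StudyTimeline, list[VisitRecord], dict, PatientTruth]:
    rng = np.random.default_rng(seq)
    baseline_days = int(rng.integers(params.baseline_days_min, params.baseline_days_max + 1))
    enrollment = params.start_date
    obs_start = enrollment + dt.timedelta(days=baseline_days)
    observation_end = obs_start + dt.timedelta(days=params.observation_days - 1)
    n_days = baseline_days + params.observation_days
    dates = [enrollment + dt.timedelta(days=i) for i in range(n_days)]

    # latent parameters
    wear_hours = 18.0 if params.full_wear else float(rng.uniform(params.wear_hours_min, params.wear_hours_max))
    base_km = max(0.8, float(rng.normal(params.daily_distance_km_mean, params.daily_distance_km_sd)))
    stride = float(np.clip(rng.normal(params.stride_m_mean, params.stride_m_sd), 0.4, 1.0))
    hr_rest = float(np.clip(rng.normal(params.hr_rest_mean, params.hr_rest_sd), 50, 110))
    effect_km = params.treatment_effect_km * (1.0 + params.effect_sd_frac * float(rng.standard_normal()))

    # inhalation sessions (observation period only)
    sessions: list[InhalationSession] = []
    for i in range(params.observation_days):
        sessions.extend(_daily_sessions(rng, pid, obs_start + dt.timedelta(days=i), params))
    if sessions:
        treatment_start = sessions[0].start
    else:
        treatment_start = dt.datetime.combine(obs_start, dt.time(8, 0))
    timeline = StudyTimeline(pid, enrollment, treatment_start, observation_end)

    W = _WINDOW_MIN
    w = _two_peak_circadian(W) if params.circadian else np.ones(W)
    if params.day_noise_cv > 0:
        sigma = math.sqrt(math.log(1.0 + params.day_noise_cv**2))
        mult = rng.lognormal(-0.5 * sigma**2, sigma, n_days)
    else:
        mult = np.ones(n_days)
    ramp = np.zeros(n_days)
    for i in range(params.observation_days):
        ramp[baseline_days + i] = effect_km * (i + 1) / params.observation_days
    km_per_day = np.maximum(0.1, base_km + ramp)

    # steps/min rate on the (day, window-minute) grid
    base_rate = (km_per_day[:, None] * 1000.0 / stride / W) * w[None, :]

    day_idx = np.arange(n_days)
    abs_min = (day_idx[:, None] * 1440 + _WINDOW_START_MIN + np.arange(W)[None, :]).ravel()
    ends = np.array(sorted(_ceil_abs_minute(s.end, enrollment) for s in sessions), dtype=int)
    if len(ends):
        pos = np.searchsorted(ends, abs_min, side="right") - 1
        delta = np.where(pos >= 0, abs_min - ends[np.clip(pos, 0, None)], np.inf)
    else:
        delta = np.full(abs_min.shape, np.inf)
    boost = 1.0 + params.boost_amplitude * np.exp(-delta / params.boost_decay_min)
    lam = base_rate.ravel() * boost * np.repeat(mult, W)
    steps = rng.poisson(lam)
    standup_lam = (params.standups_per_day_mean / W) * np.tile(w, n_days) * np.repeat(mult, W)
    standups = rng.poisson(standup_lam)

    # noiseless expected daily distance on a full-wear basis (for recovery tests)
    expected_daily_km = (base_rate.ravel() * boost).reshape(n_days, W).sum(axis=1) * stride / 1000.0

    # wear schedule and heart rate
    worn = np.zeros(n_days * W, dtype=bool)
    for d in range(n_days):
        target = W if params.full_wear else int(np.clip(round(rng.normal(wear_hours * 60, 30)), 60, W))
        worn[d * W : (d + 1) * W] = _wear_mask(rng, target, W)
    n_worn = int(worn.sum())
    hr = hr_rest + params.hr_activity_slope * steps[worn] + rng.normal(0, params.hr_noise_sd, n_worn)
    hr = np.round(np.clip(hr, 40.0, 220.0), 1)

    t0 = np.datetime64(dt.datetime.combine(enrollment, dt.time()), "m")
    timestamps = t0 + abs_min[worn].astype("timedelta64[m]")
    epochs = pd.DataFrame(
        {
            "steps": steps[worn].astype(int),
            "distance_m": steps[worn] * stride,
            "standup_events": standups[worn].astype(int),
            "heart_rate_bpm": hr,
        },
        index=pd.DatetimeIndex(timestamps, name="timestamp"),
    )
    stream = SampleStream(patient_id=pid, epochs=epochs)

    visits, traces = _generate_visits(rng, pid, params, enrollment, observation_end,
                                      base_km, stride, hr_rest, effect_km)
    truth = PatientTruth(
        patient_id=pid,
        stride_m=stride,
        hr_rest_bpm=hr_rest,
        base_daily_km=base_km,
        effect_km=effect_km,
        wear_hours=wear_hours,
        first_date=enrollment,
        expected_daily_km=expected_daily_km,
    )
    return stream, sessions, timeline, visits, traces, truth


def _generate_visits(
    rng: np.random.Generator,
    pid: str,
    params: CohortParams,
    enrollment: dt.date,
    observation_end: dt.date,
    base_km: float,
    stride: float,
    hr_rest: float,
    effect_km: float,
) -> tuple[list[VisitRecord], dict]:
    steps_i = int(np.clip(round(rng.normal(480 + 20 * (base_km - params.daily_distance_km_mean), 30)), 250, 750))
    rel_change = effect_km / base_km + float(rng.normal(0, 0.06))
    steps_f = int(np.clip(round(steps_i * (1 + rel_change)), 200, 850))
    trad_i = round(steps_i * stride * (1 + rng.normal(0, 0.04)), 1)
    trad_f = round(steps_f * stride * (1 + rng.normal(0, 0.04)), 1)

    borg_i = float(np.clip(round(rng.normal(5.0, 1.8) * 2) / 2, 0, 10))
    borg_f = float(np.clip(borg_i + round(rng.normal(-0.5 - 4 * rel_change, 1.2) * 2) / 2, 0, 10))
    who_i = "III" if rng.random() < 0.8 else "II"
    who_f = "II" if (who_i == "III" and rel_change > 0.03 and rng.random() < 0.35) else who_i
    use_bnp = rng.random() < 0.4
    marker_i = float(np.round(rng.lognormal(math.log(180 if use_bnp else 1500), 0.9), 0))
    marker_f = float(np.round(max(5.0, marker_i * (1 - 1.5 * rel_change + rng.normal(0, 0.25))), 0))
    eq_i = float(np.clip(round(rng.normal(0.85, 0.12), 2), -0.3, 1.0))
    eq_f = float(np.clip(round(eq_i + 0.02 + rng.normal(0, 0.05), 2), -0.3, 1.0))
    psqi_i = int(np.clip(round(rng.normal(7, 3)), 0, 21))
    psqi_f = int(np.clip(psqi_i + round(rng.normal(-0.8, 1.5)), 0, 21))

    def rec(visit, six, borg, who, eq, psqi):
        return VisitRecord(
            patient_id=pid,
            visit=visit,
            six_mwd_m=six,
            borg=borg,
            who_fc=who,
            bnp_ng_l=(marker_i if visit == "initial" else marker_f) if use_bnp else None,
            ntprobnp_ng_l=None if use_bnp else (marker_i if visit == "initial" else marker_f),
            eq5d_index=eq,
            psqi_global=psqi,
        )

    visits = [
        rec("initial", trad_i, borg_i, who_i, eq_i, psqi_i),
        rec("final", trad_f, borg_f, who_f, eq_f, psqi_f),
    ]

    chrono = float(np.clip(rng.normal(35, 8), 15, 60))

    def trace(visit, date, steps_test, tau):
        start = dt.datetime.combine(date, dt.time(10, 0))
        pre_hr = np.round(np.clip(hr_rest + rng.normal(0, 2, 5), 40, 220), 1)
        k = np.arange(1, 7)
        in_hr = np.round(np.clip(hr_rest + chrono * (1 - np.exp(-k / 1.5)) + rng.normal(0, 2, 6), 40, 230), 1)
        t = np.arange(1, 6)
        post_hr = np.round(np.clip(hr_rest + (in_hr[-1] - hr_rest) * np.exp(-t / tau) + rng.normal(0, 2, 5), 40, 230), 1)
        return WalkTestTrace(
            patient_id=pid,
            visit=visit,
            test_start=start,
            pre_hr=pre_hr,
            pre_steps=np.zeros(5),
            in_hr=in_hr,
            post_hr=post_hr,
            steps_in_test=steps_test,
            traditional_distance_m=trad_i if visit == "initial" else trad_f,
        )

    traces = {
        (pid, "initial"): trace("initial", enrollment, steps_i, 1.3),
        (pid, "final"): trace("final", observation_end, steps_f, 2.0),
    }
    return visits, traces


def generate_cohort(
    params: CohortParams, out_dir: Optional[str | Path] = None
) -> tuple[Cohort, GroundTruth]:
    """Generate a full synthetic cohort; optionally write it to a directory."""
    root = np.random.SeedSequence(params.rng_seed)
    spawns = root.spawn(params.n_patients)
    streams: dict[str, SampleStream] = {}
    sessions: dict[str, list[InhalationSession]] = {}
    timelines: dict[str, StudyTimeline] = {}
    visits: list[VisitRecord] = []
    traces: dict[tuple[str, str], WalkTestTrace] = {}
    truth = GroundTruth(params=params)
    for i, seq in enumerate(spawns):
        pid = f"P{i + 1:03d}"
        stream, sess, timeline, vrecs, trc, pt = _generate_patient(pid, seq, params)
        streams[pid] = stream
        sessions[pid] = sess
        timelines[pid] = timeline
        visits.extend(vrecs)
        traces.update(trc)
        truth.patients[pid] = pt
    cohort = Cohort(
        streams=streams, sessions=sessions, timelines=timelines, visits=visits, traces=traces
    )
    if out_dir is not None:
        out_dir = Path(out_dir)
        write_cohort(cohort, out_dir)
        truth.to_json(out_dir / "ground_truth.json")
    return cohort, truth


def degrade_wear(
    cohort: Cohort,
    target_fraction: float | tuple[float, float],
    seed: int,
) -> Cohort:
    """Randomly mask worn minutes down to a target daily wear fraction.

    ``target_fraction`` may be a scalar or a (low, high) range sampled
    uniformly per patient-day. Days already at or below the target are left
    untouched (masking only removes wear). Masked minutes are dropped from
    the stream entirely; logs, timelines and visits are unchanged.
    """
    if isinstance(target_fraction, tuple):
        lo, hi = target_fraction
    else:
        lo = hi = float(target_fraction)
    if not (0.0 < lo <= hi <= 1.0):
        raise ValidationError("target_fraction must lie in (0, 1]")
    rng = np.random.default_rng(seed)
    new_streams: dict[str, SampleStream] = {}
    for pid in sorted(cohort.streams):
        df = cohort.streams[pid].epochs
        keep = np.ones(len(df), dtype=bool)
        day_codes = df.index.normalize().factorize(sort=True)[0]
        order = np.argsort(day_codes, kind="stable")
        counts = np.bincount(day_codes)
        for sel in np.split(order, np.cumsum(counts)[:-1]):
            f = float(rng.uniform(lo, hi))
            target = int(math.ceil(f * _WINDOW_MIN))
            if len(sel) > target:
                drop = rng.choice(sel, size=len(sel) - target, replace=False)
                keep[drop] = False
        new_streams[pid] = SampleStream(patient_id=pid, epochs=df.iloc[keep].copy())
    return Cohort(
        streams=new_streams,
        sessions=cohort.sessions,
        timelines=cohort.timelines,
        visits=cohort.visits,
        traces=cohort.traces,
    )


def expected_alignment_curve(
    truth: PatientTruth,
    params: CohortParams,
    n_bins: int = 12,
    bin_minutes: int = 15,
) -> np.ndarray:
    """Expected post-inhalation distance per bin on a flat background.

    Valid when the generator ran with ``circadian=False``, ``day_noise_cv=0``
    and ``treatment_effect_km=0`` and session windows do not overlap: the
    expected distance in bin b is the flat per-minute rate times the mean
    boost factor over that bin's minute offsets.
    """
    rate_m_per_min = truth.base_daily_km * 1000.0 / _WINDOW_MIN
    offsets = np.arange(n_bins * bin_minutes, dtype=float)
    factor = 1.0 + params.boost_amplitude * np.exp(-offsets / params.boost_decay_min)
    return rate_m_per_min * factor.reshape(n_bins, bin_minutes).sum(axis=1)
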