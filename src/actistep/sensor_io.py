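"""Readers and writers for sensor streams, inhalation logs, visits and traces.

All files are UTF-8 CSV with `.` decimal separator and ISO-8601 timestamps.
Readers are strict: an invalid row raises (naming the row) rather than being
silently dropped, so accepted rows always account for the whole input.

A cohort directory holds::

    cohort/
      timeline.csv                  patient_id,enrollment_date,treatment_start,observation_end
      visits.csv                    one row per (patient, visit)
      streams/<patient_id>.csv      timestamp,steps,distance_m,standup_events,heart_rate_bpm
      inhalations/<patient_id>.csv  start,end,complete,dose_ug
      walk_tests/<pid>_<visit>.csv  timestamp,phase,steps,heart_rate_bpm   (optional)
      ground_truth.json             (optional, synthetic cohorts only)
"""

from __future__ import annotations

import datetime as dt
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .types import (
    Cohort,
    EPOCH_COLUMNS,
    InhalationSession,
    ParseError,
    SampleStream,
    StudyTimeline,
    ValidationError,
    VisitRecord,
    WalkTestTrace,
)

_STREAM_HEADER = ["timestamp", *EPOCH_COLUMNS]
_VISIT_NUMERIC = (
    "six_mwd_m",
    "borg",
    "bnp_ng_l",
    "ntprobnp_ng_l",
    "eq5d_index",
    "psqi_global",
)


def _parse_timestamps(raw: pd.Series, what: str) -> pd.Series:
    ts = pd.to_datetime(raw, errors="coerce")
    bad = ts.isna() & raw.notna()
    if bad.any():
        row = int(np.flatnonzero(bad.to_numpy())[0])
        raise ParseError(
            f"{what}: malformed timestamp {raw.iloc[row]!r} in data row {row + 1}"
        )
    if ts.isna().any():
        row = int(np.flatnonzero(ts.isna().to_numpy())[0])
        raise ParseError(f"{what}: empty timestamp in data row {row + 1}")
    return ts


def read_sample_stream(path: str | Path, patient_id: str) -> SampleStream:
    """Read a minute-epoch CSV into a validated :class:`SampleStream`."""
    df = pd.read_csv(path)
    missing = [c for c in _STREAM_HEADER if c not in df.columns]
    if missing:
        raise ParseError(f"{path}: missing columns {missing}")
    ts = _parse_timestamps(df["timestamp"], str(path))
    out = pd.DataFrame(
        {
            "steps": pd.to_numeric(df["steps"]).to_numpy(),
            "distance_m": pd.to_numeric(df["distance_m"]).to_numpy(dtype=float),
            "standup_events": pd.to_numeric(df["standup_events"]).to_numpy(),
            "heart_rate_bpm": pd.to_numeric(df["heart_rate_bpm"]).to_numpy(dtype=float),
        },
        index=pd.DatetimeIndex(ts, name="timestamp"),
    )
    return SampleStream(patient_id=patient_id, epochs=out)


def write_sample_stream(stream: SampleStream, path: str | Path) -> None:
    df = stream.epochs.copy()
    df.index = df.index.strftime("%Y-%m-%dT%H:%M:%S")
    df.index.name = "timestamp"
    df.to_csv(path, float_format="%.12g")


def read_inhalation_log(path: str | Path, patient_id: str) -> list[InhalationSession]:
    """Read a nebulizer log; sessions are returned sorted by start time."""
    df = pd.read_csv(path)
    for col in ("start", "end", "complete", "dose_ug"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    start = _parse_timestamps(df["start"], f"{path} (start)")
    end = _parse_timestamps(df["end"], f"{path} (end)")
    complete = df["complete"].map(_parse_bool)
    sessions = [
        InhalationSession(
            patient_id=patient_id,
            start=s.to_pydatetime(),
            end=e.to_pydatetime(),
            complete=bool(c),
            dose_ug=float(d),
        )
        for s, e, c, d in zip(start, end, complete, df["dose_ug"])
    ]
    return sorted(sessions, key=lambda s: s.start)


def _parse_bool(value) -> bool:
    if isinstance(value, (bool, np.bool_)):
        return bool(value)
    text = str(value).strip().lower()
    if text in {"true", "1", "yes"}:
        return True
    if text in {"false", "0", "no"}:
        return False
    raise ParseError(f"cannot parse boolean value {value!r}")


def write_inhalation_log(sessions: list[InhalationSession], path: str | Path) -> None:
    rows = [
        {
            "start": s.start.isoformat(),
            "end": s.end.isoformat(),
            "complete": s.complete,
            "dose_ug": s.dose_ug,
        }
        for s in sorted(sessions, key=lambda s: s.start)
    ]
    pd.DataFrame(rows, columns=["start", "end", "complete", "dose_ug"]).to_csv(
        path, index=False, float_format="%.12g"
    )


def read_visits(path: str | Path) -> list[VisitRecord]:
    """Read visit records; empty cells map to absent, never to zero."""
    df = pd.read_csv(path)
    for col in ("patient_id", "visit"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    seen: set[tuple[str, str]] = set()
    records: list[VisitRecord] = []
    for _, row in df.iterrows():
        key = (str(row["patient_id"]), str(row["visit"]))
        if key in seen:
            raise ValidationError(f"duplicate visit record for {key}")
        seen.add(key)
        kwargs: dict = {"patient_id": key[0], "visit": key[1]}
        for col in _VISIT_NUMERIC:
            val = row.get(col)
            if val is None or (isinstance(val, float) and np.isnan(val)) or val == "":
                kwargs[col] = None
            elif col == "psqi_global":
                kwargs[col] = int(val)
            else:
                kwargs[col] = float(val)
        fc = row.get("who_fc")
        kwargs["who_fc"] = None if pd.isna(fc) or fc == "" else str(fc)
        records.append(VisitRecord(**kwargs))
    return records


def write_visits(records: list[VisitRecord], path: str | Path) -> None:
    cols = ["patient_id", "visit", *(_VISIT_NUMERIC[:2]), "who_fc", *(_VISIT_NUMERIC[2:])]
    rows = []
    for r in records:
        rows.append(
            {
                "patient_id": r.patient_id,
                "visit": r.visit,
                "six_mwd_m": r.six_mwd_m,
                "borg": r.borg,
                "who_fc": r.who_fc,
                "bnp_ng_l": r.bnp_ng_l,
                "ntprobnp_ng_l": r.ntprobnp_ng_l,
                "eq5d_index": r.eq5d_index,
                "psqi_global": r.psqi_global,
            }
        )
    pd.DataFrame(rows, columns=cols).to_csv(path, index=False, float_format="%.12g")


def read_timelines(path: str | Path) -> dict[str, StudyTimeline]:
    df = pd.read_csv(path)
    timelines: dict[str, StudyTimeline] = {}
    for _, row in df.iterrows():
        pid = str(row["patient_id"])
        if pid in timelines:
            raise ValidationError(f"duplicate timeline for patient {pid}")
        timelines[pid] = StudyTimeline(
            patient_id=pid,
            enrollment_date=dt.date.fromisoformat(str(row["enrollment_date"])),
            treatment_start=dt.datetime.fromisoformat(str(row["treatment_start"])),
            observation_end=dt.date.fromisoformat(str(row["observation_end"])),
        )
    return timelines


def write_timelines(timelines: dict[str, StudyTimeline], path: str | Path) -> None:
    rows = [
        {
            "patient_id": t.patient_id,
            "enrollment_date": t.enrollment_date.isoformat(),
            "treatment_start": t.treatment_start.isoformat(),
            "observation_end": t.observation_end.isoformat(),
        }
        for t in (timelines[k] for k in sorted(timelines))
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_walk_trace(
    path: str | Path,
    patient_id: str,
    visit: str,
    traditional_distance_m: Optional[float] = None,
) -> WalkTestTrace:
    """Read a phase-labelled per-minute walk-test trace.

    Rows carry ``phase`` in {pre, test, post}; the test phase must span
    exactly six minutes.
    """
    df = pd.read_csv(path)
    for col in ("timestamp", "phase", "steps", "heart_rate_bpm"):
        if col not in df.columns:
            raise ParseError(f"{path}: missing column {col!r}")
    ts = _parse_timestamps(df["timestamp"], str(path))
    df = df.assign(timestamp=ts).sort_values("timestamp")
    pre = df[df["phase"] == "pre"]
    test = df[df["phase"] == "test"]
    post = df[df["phase"] == "post"]
    if len(test) != 6:
        raise ValidationError(f"{path}: test phase must have 6 minutes, got {len(test)}")
    return WalkTestTrace(
        patient_id=patient_id,
        visit=visit,
        test_start=test["timestamp"].iloc[0].to_pydatetime(),
        pre_hr=pre["heart_rate_bpm"].to_numpy(dtype=float),
        pre_steps=pre["steps"].to_numpy(dtype=float),
        in_hr=test["heart_rate_bpm"].to_numpy(dtype=float),
        post_hr=post["heart_rate_bpm"].to_numpy(dtype=float),
        steps_in_test=int(test["steps"].sum()),
        traditional_distance_m=traditional_distance_m,
    )


def write_walk_trace(trace: WalkTestTrace, path: str | Path) -> None:
    rows = []
    n_pre = len(trace.pre_hr)
    for i in range(n_pre):
        t = trace.test_start - dt.timedelta(minutes=n_pre - i)
        rows.append((t, "pre", trace.pre_steps[i], trace.pre_hr[i]))
    per_min = np.diff(np.round(np.linspace(0, trace.steps_in_test, 7))).astype(int)
    for i in range(6):
        t = trace.test_start + dt.timedelta(minutes=i)
        rows.append((t, "test", per_min[i], trace.in_hr[i]))
    for i in range(len(trace.post_hr)):
        t = trace.test_end + dt.timedelta(minutes=i + 1)
        rows.append((t, "post", 0, trace.post_hr[i]))
    df = pd.DataFrame(rows, columns=["timestamp", "phase", "steps", "heart_rate_bpm"])
    df["timestamp"] = df["timestamp"].map(lambda t: t.isoformat())
    df.to_csv(path, index=False, float_format="%.12g")


def load_cohort(directory: str | Path) -> Cohort:
    """Load a cohort directory into memory."""
    directory = Path(directory)
    timelines = read_timelines(directory / "timeline.csv")
    visits_path = directory / "visits.csv"
    visits = read_visits(visits_path) if visits_path.exists() else []
    streams: dict[str, SampleStream] = {}
    sessions: dict[str, list[InhalationSession]] = {}
    for pid in sorted(timelines):
        spath = directory / "streams" / f"{pid}.csv"
        if spath.exists():
            streams[pid] = read_sample_stream(spath, pid)
        ipath = directory / "inhalations" / f"{pid}.csv"
        if ipath.exists():
            sessions[pid] = read_inhalation_log(ipath, pid)
    traces: dict[tuple[str, str], WalkTestTrace] = {}
    tdir = directory / "walk_tests"
    if tdir.is_dir():
        by_key = {(v.patient_id, v.visit): v for v in visits}
        for f in sorted(tdir.glob("*.csv")):
            pid, _, visit = f.stem.rpartition("_")
            rec = by_key.get((pid, visit))
            traces[(pid, visit)] = read_walk_trace(
                f, pid, visit, rec.six_mwd_m if rec else None
            )
    return Cohort(
        streams=streams,
        sessions=sessions,
        timelines=timelines,
        visits=visits,
        traces=traces,
    )


def write_cohort(cohort: Cohort, directory: str | Path) -> None:
    directory = Path(directory)
    (directory / "streams").mkdir(parents=True, exist_ok=True)
    (directory / "inhalations").mkdir(exist_ok=True)
    write_timelines(cohort.timelines, directory / "timeline.csv")
    write_visits(cohort.visits, directory / "visits.csv")
    for pid in sorted(cohort.streams):
        write_sample_stream(cohort.streams[pid], directory / "streams" / f"{pid}.csv")
    for pid in sorted(cohort.sessions):
        write_inhalation_log(cohort.sessions[pid], directory / "inhalations" / f"{pid}.csv")
    if cohort.traces:
        (directory / "walk_tests").mkdir(exist_ok=True)
        for (pid, visit) in sorted(cohort.traces):
            write_walk_trace(
                cohort.traces[(pid, visit)],
                directory / "walk_tests" / f"{pid}_{visit}.csv",
            )


def validate_cohort(directory: str | Path) -> list[str]:
    """Check a cohort directory; returns a list of problems (empty = valid)."""
    directory = Path(directory)
    problems: list[str] = []
    if not (directory / "timeline.csv").exists():
        return [f"{directory}: timeline.csv not found"]
    try:
        cohort = load_cohort(directory)
    except (ParseError, ValidationError, OSError) as exc:
        return [str(exc)]
    for pid in cohort.patient_ids:
        if pid not in cohort.streams:
            problems.append(f"{pid}: no sensor stream")
        if pid not in cohort.sessions:
            problems.append(f"{pid}: no inhalation log")
        for visit in ("initial", "final"):
            if cohort.visit(pid, visit) is None:
                problems.append(f"{pid}: no {visit} visit record")
    return problems
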