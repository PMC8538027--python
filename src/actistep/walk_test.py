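"""Digital six-minute-walk-distance and heart-rate endpoints.

The digital 6MWD is an explicit stride model: distance = steps x stride,
with the stride either a cohort-wide constant (default 0.78 m, a healthy-
adult value, which over-estimates distance in patients with a shortened
gait) or a per-patient stride. Resting heart rate is the mean over worn
zero-step minutes, the simplest observable proxy for "at rest". The
chronotropic response is peak walking heart rate minus resting heart rate.
Heart-rate recovery is reported as HR(end + t) - HR(end) at half-minute
offsets; negative values mean the heart rate is falling back (recovering).
"""

from __future__ import annotations

import datetime as dt
from typing import Optional

import numpy as np

from .config import AnalysisConfig
from .types import SampleStream, WalkTestEndpoints, WalkTestTrace


def digital_6mwd(
    trace: WalkTestTrace, config: AnalysisConfig, stride_m: Optional[float] = None
) -> Optional[float]:
    """Estimated walk distance in meters: steps x stride.

    ``stride_m`` overrides the configured constant stride (individualized
    step length).
    """
    if trace.steps_in_test is None:
        return None
    stride = stride_m if stride_m is not None else config.stride_length_m
    return float(trace.steps_in_test) * float(stride)


def hr_during_test(trace: WalkTestTrace) -> Optional[np.ndarray]:
    """Per-minute HR change: HR(minute k) - HR(minute -1), k = 1..6."""
    if len(trace.pre_hr) == 0 or np.isnan(trace.pre_hr[-1]):
        return None
    return trace.in_hr - trace.pre_hr[-1]


def resting_hr_from_trace(trace: WalkTestTrace, config: AnalysisConfig) -> Optional[float]:
    """Pre-test resting HR: mean over zero-step minutes in the window before start.

    Uses the last ``resting_hr_window_min`` pre-test minutes; absent when no
    zero-step minute with an HR sample falls in that window.
    """
    window = config.resting_hr_window_min
    hr = trace.pre_hr[-window:]
    steps = trace.pre_steps[-window:]
    ok = (steps == 0) & ~np.isnan(hr)
    if not ok.any():
        return None
    return float(np.mean(hr[ok]))


def daily_resting_hr(
    stream: SampleStream, date: dt.date, config: AnalysisConfig
) -> Optional[float]:
    """Daily resting HR: mean HR over worn zero-step minutes in the window.

    Requires at least ``resting_hr_window_min`` qualifying minutes.
    """
    from .wear_aggregation import _window_slice

    day = _window_slice(stream, date, config)
    worn_rest = day[(day["heart_rate_bpm"].notna()) & (day["steps"] == 0)]
    if len(worn_rest) < config.resting_hr_window_min:
        return None
    return float(worn_rest["heart_rate_bpm"].mean())


def chronotropic_response(
    trace: WalkTestTrace, config: AnalysisConfig, resting_hr_bpm: Optional[float] = None
) -> Optional[float]:
    """Peak walking heart rate minus resting heart rate, in bpm."""
    resting = (
        resting_hr_bpm if resting_hr_bpm is not None else resting_hr_from_trace(trace, config)
    )
    if resting is None or len(trace.in_hr) == 0 or np.isnan(trace.in_hr).all():
        return None
    return float(np.nanmax(trace.in_hr) - resting)


def recovery_curve(trace: WalkTestTrace) -> tuple[np.ndarray, np.ndarray]:
    """Post-test HR relative to end-of-test HR at 0.5-min offsets.

    HR is taken on the minute grid (offset 0 = last in-test minute, offset k
    = k-th post-test minute) with linear interpolation at half-minute
    offsets, out to 3 minutes or the available post-test coverage,
    whichever is shorter. Returns (offsets_min, delta_bpm).
    """
    hr_end = trace.in_hr[-1]
    grid = np.concatenate([[hr_end], trace.post_hr])
    max_offset = min(3.0, float(len(trace.post_hr)))
    offsets = np.arange(0.5, max_offset + 1e-9, 0.5)
    deltas = np.interp(offsets, np.arange(len(grid)), grid) - hr_end
    return offsets, deltas


def walk_endpoints(
    trace: WalkTestTrace, config: AnalysisConfig, stride_m: Optional[float] = None
) -> WalkTestEndpoints:
    """Assemble all digital walk-test endpoints for one trace."""
    resting = resting_hr_from_trace(trace, config)
    offsets, curve = recovery_curve(trace)
    return WalkTestEndpoints(
        patient_id=trace.patient_id,
        visit=trace.visit,
        digital_6mwd_m=digital_6mwd(trace, config, stride_m),
        resting_hr_bpm=resting,
        per_minute_hr_change=hr_during_test(trace),
        chronotropic_response_bpm=chronotropic_response(trace, config, resting),
        recovery_offsets_min=offsets,
        recovery_curve=curve,
    )
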