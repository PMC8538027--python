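"""Post-inhalation binning, exclusion rules, and three-level averaging."""

import datetime as dt

import numpy as np
import pytest

from actistep.config import AnalysisConfig
from actistep.event_alignment import (
    align_sessions,
    average_curves,
    cohort_behavior,
    inhalation_behavior,
)
from actistep.types import EmptyCurveError, InhalationSession, SessionCurve

from conftest import make_stream, make_timeline


def session(pid="P1", start="2023-01-02T08:00", minutes=6.0):
    s = dt.datetime.fromisoformat(start)
    return InhalationSession(pid, s, s + dt.timedelta(minutes=minutes), True, 2.5)


def brute_force_bins(stream, sess, config):
    """Independent oracle: enumerate each bin minute by timestamp lookup."""
    end = sess.end
    if end.second or end.microsecond:
        end = (end + dt.timedelta(minutes=1)).replace(second=0, microsecond=0)
    epochs = stream.epochs
    bins, worn_flags = [], []
    for b in range(config.n_bins):
        vals = np.zeros(config.bin_minutes)
        worn = np.zeros(config.bin_minutes, dtype=bool)
        for m in range(config.bin_minutes):
            t = end + dt.timedelta(minutes=b * config.bin_minutes + m)
            if t in epochs.index and not np.isnan(epochs.at[t, "heart_rate_bpm"]):
                worn[m] = True
                vals[m] = epochs.at[t, "distance_m"]
        bins.append(np.sum(vals))
        worn_flags.append(worn)
    followup = all(w.all() for w in worn_flags[1:])
    return np.array(bins), followup, not worn_flags[0].all()


class TestAlignSessions:
    def test_constant_rate_full_wear_gives_150_per_bin(self, config):
        stream = make_stream("P1", "2023-01-02T06:00", 1080, steps=10, distance_m=10.0)
        [curve] = align_sessions(stream, [session()], config)
        assert curve.included and not curve.partial_first_bin
        np.testing.assert_array_equal(curve.bins, np.full(12, 150.0))

    def test_wear_gap_in_followup_excludes_session(self, config):
        hr = np.full(1080, 80.0)
        # session ends 08:06; minute 170 after end = 10:56 = index 296
        hr[296] = np.nan
        stream = make_stream("P1", "2023-01-02T06:00", 1080, distance_m=10.0, hr=hr)
        [curve] = align_sessions(stream, [session()], config)
        assert not curve.included and curve.reason == "unworn_followup"

    def test_partial_first_bin_tolerated_with_raw_sum(self, config):
        hr = np.full(1080, 80.0)
        hr[127] = np.nan  # 08:07, inside bin 1 (08:06-08:20)
        stream = make_stream("P1", "2023-01-02T06:00", 1080, distance_m=10.0, hr=hr)
        [curve] = align_sessions(stream, [session()], config)
        assert curve.included and curve.partial_first_bin
        assert curve.bins[0] == pytest.approx(140.0)  # raw sum, not rescaled
        np.testing.assert_allclose(curve.bins[1:], 150.0)

    def test_strict_mode_excludes_on_partial_first_bin(self):
        config = AnalysisConfig(strict_alignment=True)
        hr = np.full(1080, 80.0)
        hr[127] = np.nan
        stream = make_stream("P1", "2023-01-02T06:00", 1080, distance_m=10.0, hr=hr)
        [curve] = align_sessions(stream, [session()], config)
        assert not curve.included

    def test_session_ending_mid_minute_rounds_up(self, config):
        stream = make_stream("P1", "2023-01-02T06:00", 1080, distance_m=10.0)
        [a] = align_sessions(stream, [session(minutes=5.5)], config)  # ends 08:05:30
        [b] = align_sessions(stream, [session(minutes=6.0)], config)  # ends 08:06
        np.testing.assert_array_equal(a.bins, b.bins)

    def test_session_beyond_stream_coverage_excluded_with_reason(self, config):
        stream = make_stream("P1", "2023-01-02T06:00", 200)
        [curve] = align_sessions(stream, [session(start="2023-01-02T09:00")], config)
        assert not curve.included and curve.reason == "beyond_coverage"

    def test_overlapping_windows_both_included_and_match_oracle(self, config):
        rng = np.random.default_rng(3)
        steps = rng.integers(0, 20, 1080)
        stream = make_stream(
            "P1", "2023-01-02T06:00", 1080, steps=steps, distance_m=steps * 0.71
        )
        sessions = [session(start="2023-01-02T08:00"), session(start="2023-01-02T08:30")]
        curves = align_sessions(stream, sessions, config)
        assert all(c.included for c in curves)
        for c, s in zip(curves, sessions):
            bins, followup, _ = brute_force_bins(stream, s, config)
            assert followup
            np.testing.assert_array_equal(c.bins, bins)

    def test_translation_invariance(self, config):
        rng = np.random.default_rng(4)
        steps = rng.integers(0, 20, 400)
        hr = np.where(rng.random(400) < 0.1, np.nan, 80.0)
        stream = make_stream("P1", "2023-01-02T06:00", 400, steps=steps, hr=hr)
        shifted = make_stream("P1", "2023-01-02T06:37", 400, steps=steps, hr=hr)
        [a] = align_sessions(stream, [session(start="2023-01-02T07:00")], config)
        [b] = align_sessions(shifted, [session(start="2023-01-02T07:37")], config)
        assert a.included == b.included
        np.testing.assert_array_equal(a.bins, b.bins)


def curve_of(pid, day, bins):
    s = session(pid, f"2023-01-{day:02d}T08:00")
    return SessionCurve(pid, s, np.asarray(bins, dtype=float), True, None, False)


class TestAverageCurves:
    def test_within_day_mean(self):
        c = average_curves(
            [curve_of("P1", 2, [100] * 12), curve_of("P1", 2, [200] * 12)]
        )
        assert c.cohort_means[0] == pytest.approx(150.0)
        assert len(c.per_patient_day_curves) == 1

    def test_across_patient_days_mean(self):
        c = average_curves([curve_of("P1", 2, [150] * 12), curve_of("P2", 3, [50] * 12)])
        assert c.cohort_means[0] == pytest.approx(100.0)

    def test_three_level_average_matches_loop_oracle(self):
        rng = np.random.default_rng(5)
        curves = []
        for pid in ("P1", "P2", "P3"):
            for day in (2, 3, 4):
                for _ in range(rng.integers(1, 4)):
                    curves.append(curve_of(pid, day, rng.uniform(0, 100, 12)))
        c = average_curves(curves)
        # explicit three-level loop oracle
        by_pd = {}
        for cv in curves:
            by_pd.setdefault((cv.patient_id, cv.day), []).append(cv.bins)
        day_means = [np.mean(np.array(v), axis=0) for v in by_pd.values()]
        oracle = np.mean(np.array(day_means), axis=0)
        np.testing.assert_allclose(c.cohort_means, oracle, rtol=1e-12)

    def test_zero_included_sessions_raises(self):
        bad = curve_of("P1", 2, [0] * 12)
        bad.included = False
        with pytest.raises(EmptyCurveError):
            average_curves([bad])

    def test_inclusion_accounting(self):
        bad = curve_of("P1", 2, [0] * 12)
        bad.included = False
        bad.reason = "unworn_followup"
        c = average_curves([curve_of("P1", 2, [1] * 12), bad])
        assert c.included_inhalations == 1 and c.excluded_inhalations == 1


class TestInhalationBehavior:
    def test_daily_percent_complete(self):
        tl = make_timeline("P1", "2023-01-02", "2023-01-10T08:00", "2023-01-11")
        sessions = [
            InhalationSession(
                "P1",
                dt.datetime(2023, 1, 10, 8 + i, 0),
                dt.datetime(2023, 1, 10, 8 + i, 6),
                i < 4,
                2.5,
            )
            for i in range(5)
        ]
        out = inhalation_behavior(sessions, tl)
        assert out["median_daily_pct_complete"] == pytest.approx(80.0)

    def test_median_daily_count(self):
        tl = make_timeline("P1", "2023-01-02", "2023-01-10T08:00", "2023-01-12")
        sessions = []
        for day, n in zip((10, 11, 12), (5, 5, 6)):
            for i in range(n):
                sessions.append(
                    InhalationSession(
                        "P1",
                        dt.datetime(2023, 1, day, 8, 10 * i),
                        dt.datetime(2023, 1, day, 8, 10 * i + 5),
                        True,
                        2.5,
                    )
                )
        out = inhalation_behavior(sessions, tl)
        assert out["median_daily_sessions"] == 5.0

    def test_cohort_medians_match_brute_force(self):
        timelines = {
            p: make_timeline(p, "2023-01-02", "2023-01-10T08:00", "2023-01-12")
            for p in ("P1", "P2")
        }
        sessions_by = {}
        rng = np.random.default_rng(6)
        for p in timelines:
            sess = []
            for day in (10, 11, 12):
                for i in range(int(rng.integers(1, 5))):
                    sess.append(
                        InhalationSession(
                            p,
                            dt.datetime(2023, 1, day, 9, 12 * i),
                            dt.datetime(2023, 1, day, 9, 12 * i + 6),
                            bool(rng.random() < 0.8),
                            2.5,
                        )
                    )
            sessions_by[p] = sess
        out = cohort_behavior(sessions_by, timelines)
        # brute force per-patient median of daily counts, then cohort median
        expected = []
        for p, sess in sessions_by.items():
            counts = {d: 0 for d in (10, 11, 12)}
            for s in sess:
                counts[s.end.day] += 1
            expected.append(np.median(list(counts.values())))
        assert out["median_daily_sessions"]["median"] == pytest.approx(
            np.median(expected)
        )

    def test_patient_without_sessions_is_absent(self):
        tl = make_timeline("P1", "2023-01-02", "2023-01-10T08:00", "2023-01-12")
        assert inhalation_behavior([], tl) is None
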