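import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from feedmark import events as ev
from feedmark import synthetic as syn
from feedmark.errors import AnalysisError, ConfigError
from feedmark.imaging_io import LeafAreaSeries


def _series(values, interval=1.0):
    return LeafAreaSeries(
        "t", area_px=np.asarray(values, float), mm_per_px=1.0, frame_interval=interval
    )


class TestDiffSeries:
    @pytest.mark.parametrize(
        "s,expected",
        [
            ([10, 10, 10], [0, 0]),
            ([10, 9.5, 9.5], [0.5, 0]),
        ],
    )
    def test_hand_examples(self, s, expected):
        assert np.allclose(ev.diff_series(_series(s)), expected)

    def test_units_divide_by_frame_interval(self):
        d = ev.diff_series(_series([10, 9], interval=2.0))
        assert d[0] == pytest.approx(0.5)  # mm² per minute, not per frame

    def test_too_short_series_rejected(self):
        with pytest.raises(AnalysisError):
            ev.diff_series(_series([10]))

    @settings(deadline=None, max_examples=50)
    @given(st.lists(st.floats(0, 100, allow_nan=False), min_size=2, max_size=40))
    def test_telescoping_identity(self, values):
        s = _series(values)
        assert np.sum(ev.diff_series(s)) == pytest.approx(
            values[0] - values[-1], abs=1e-9
        )


class TestDetectEvents:
    def test_single_run_hand_oracle(self):
        # run {0.5, 0.6}: duration 2 min, area 1.1 mm², rate 0.55; the two
        # drops are observed arriving at frames 3 and 4
        d = np.array([0, 0.5, 0.6, 0, 0.05, 0])
        (e,) = ev.detect_events(d, threshold=0.2)
        assert (e.start_frame, e.end_frame) == (3, 4)
        assert e.duration_min == pytest.approx(2.0)
        assert e.area_mm2 == pytest.approx(1.1)
        assert e.rate_mm2_per_min == pytest.approx(0.55)

    def test_all_zero_series_yields_no_events(self):
        assert ev.detect_events(np.zeros(10)) == []

    def test_separated_runs_are_distinct_maximal_events(self):
        d = np.array([0.3, 0, 0.3])
        evs = ev.detect_events(d, threshold=0.2)
        assert len(evs) == 2
        assert all(e.duration_min == 1.0 for e in evs)

    def test_exceed_is_strict(self):
        assert ev.detect_events(np.array([0.2, 0.2]), threshold=0.2) == []

    def test_min_run_discards_short_runs(self):
        d = np.array([0.5, 0, 0.5, 0.5])
        evs = ev.detect_events(d, threshold=0.2, min_run=2)
        assert len(evs) == 1 and evs[0].duration_min == 2.0

    @settings(deadline=None, max_examples=40)
    @given(
        st.lists(st.floats(0, 2, allow_nan=False), min_size=2, max_size=60),
        st.floats(0.1, 1.0),
    )
    def test_monotone_in_threshold(self, d, thr):
        d = np.asarray(d)
        low = sum(e.duration_min for e in ev.detect_events(d, threshold=thr))
        high = sum(e.duration_min for e in ev.detect_events(d, threshold=thr * 1.5))
        assert high <= low

    @settings(deadline=None, max_examples=40)
    @given(st.lists(st.floats(0, 2, allow_nan=False), min_size=2, max_size=60))
    def test_rate_times_duration_equals_area(self, d):
        for e in ev.detect_events(np.asarray(d)):
            assert e.rate_mm2_per_min * e.duration_min == pytest.approx(
                e.area_mm2, rel=1e-9
            )

    def test_conservation_events_capture_subset_of_total_loss(self):
        rng = np.random.default_rng(11)
        script = syn.random_behavior_script(rng)
        s, _ = syn.simulate_area_series(script, noise_sd=0.0)
        evs = ev.detect_events(ev.diff_series(s))
        total_loss = s.area_mm2[0] - s.area_mm2[-1]
        assert sum(e.area_mm2 for e in evs) <= total_loss + 1e-9

    def test_noise_free_recovery_is_exact_above_threshold(self):
        rng = np.random.default_rng(2)
        script = syn.random_behavior_script(rng)
        s, truth = syn.simulate_area_series(script, noise_sd=0.0)
        evs = ev.detect_events(ev.diff_series(s))
        above = [e for e in truth.events if e.rate_mm2_per_min > 0.2]
        assert len(evs) == len(above)
        for det, tru in zip(evs, above):
            assert det.duration_min == pytest.approx(tru.duration_min)
            assert det.area_mm2 == pytest.approx(tru.area_mm2, abs=1e-9)
            assert det.start_min == pytest.approx(tru.start_min)

    def test_sub_threshold_events_correctly_missed(self):
        script = syn.BehaviorScript(
            events=[
                syn.ScriptedEvent(5, 4, 0.1),  # below 0.2 threshold
                syn.ScriptedEvent(20, 4, 0.5),
            ]
        )
        s, _ = syn.simulate_area_series(script, noise_sd=0.0)
        evs = ev.detect_events(ev.diff_series(s))
        assert len(evs) == 1 and evs[0].rate_mm2_per_min == pytest.approx(0.5)


class TestIntervals:
    def _two_events(self, end_a=10, start_b=25):
        a = ev.FeedingEvent(1, 8, end_a, 3, 1.5, 0.5)
        b = ev.FeedingEvent(2, start_b, start_b + 2, 3, 1.5, 0.5)
        return [a, b]

    def test_interval_convention_end_to_start(self):
        a, b = ev.compute_intervals(self._two_events())
        assert a.interval_to_next_min == pytest.approx(15.0)
        assert not a.interval_excluded
        assert b.interval_to_next_min is None

    def test_molting_gap_excluded_but_event_retained(self):
        a, b = ev.compute_intervals(self._two_events(10, 160))
        assert a.interval_to_next_min == pytest.approx(150.0)
        assert a.interval_excluded
        summary = ev.summarize_assay([a, b])
        assert summary.n_events == 2
        assert summary.medians["interval_min"] is None  # only interval was excluded

    def test_single_event_no_interval_no_error(self):
        (a,) = ev.compute_intervals([ev.FeedingEvent(1, 3, 5, 3, 1.5, 0.5)])
        assert a.interval_to_next_min is None

    def test_schedule_gaps_reconstructed(self):
        rng = np.random.default_rng(4)
        script = syn.random_behavior_script(rng)
        s, truth = syn.simulate_area_series(script, noise_sd=0.0)
        evs = ev.compute_intervals(ev.detect_events(ev.diff_series(s)))
        detected = [e.interval_to_next_min for e in evs[:-1]]
        # the end-to-start convention reports each scripted rest plus one
        # frame interval (last observed drop -> frame after the next
        # consumption starts); the offset is constant and documented
        assert np.allclose(detected, np.asarray(truth.intervals_min) + 1.0)


class TestSummaries:
    def _ev(self, i, start_frame, duration, area):
        return ev.FeedingEvent(i, start_frame, start_frame, duration, area, area / duration)

    def test_odd_count_median(self):
        evs = [self._ev(i, 10 * i, d, 1.0) for i, d in enumerate([2, 4, 10], 1)]
        assert ev.summarize_assay(evs).medians["duration_min"] == pytest.approx(4.0)

    def test_even_count_midpoint_median(self):
        evs = [self._ev(i, 10 * i, d, 1.0) for i, d in enumerate([2, 4], 1)]
        assert ev.summarize_assay(evs).medians["duration_min"] == pytest.approx(3.0)

    def test_window_excludes_late_events_by_start_time(self):
        evs = [self._ev(1, 10, 2, 1.0), self._ev(2, 1202, 2, 9.0)]
        summary = ev.summarize_assay(evs, window=999)
        assert summary.n_events == 1
        assert summary.medians["area_mm2"] == pytest.approx(1.0)

    def test_zero_events_flagged_not_dropped(self):
        summary = ev.summarize_assay([], roi_label="cage3")
        assert summary.n_events == 0
        assert all(v is None for v in summary.medians.values())


class TestCompareGroups:
    def _summaries(self, values, group):
        return [
            ev.AssaySummary(
                f"{group}{i}", group, 5, {p: v for p in ev.PARAMETERS}
            )
            for i, v in enumerate(values)
        ]

    def test_welch_against_closed_form(self):
        a = [1.0, 2.0, 3.0, 4.0, 5.0]
        b = [2.0, 3.0, 4.0, 5.0, 6.0]
        res = ev.compare_groups(
            self._summaries(a, "wt"), self._summaries(b, "gl1"), "rate_mm2_per_min"
        )
        # independent closed-form Welch evaluation
        ma, mb = np.mean(a), np.mean(b)
        va, vb = np.var(a, ddof=1) / len(a), np.var(b, ddof=1) / len(b)
        t = (ma - mb) / np.sqrt(va + vb)
        df = (va + vb) ** 2 / (va**2 / (len(a) - 1) + vb**2 / (len(b) - 1))
        from scipy.stats import t as t_dist

        p = 2 * t_dist.sf(abs(t), df)
        assert res.t == pytest.approx(t, rel=1e-9)
        assert res.df == pytest.approx(df, rel=1e-9)
        assert res.p == pytest.approx(p, rel=1e-9)

    def test_identical_groups_t_zero_p_one(self):
        a = [1.0, 2.0, 3.0]
        res = ev.compare_groups(
            self._summaries(a, "x"), self._summaries(a, "y"), "duration_min"
        )
        assert res.t == pytest.approx(0.0)
        assert res.p == pytest.approx(1.0)

    def test_swapping_groups_negates_t_preserves_p(self):
        a = self._summaries([1.0, 2.0, 4.0], "a")
        b = self._summaries([3.0, 5.0, 6.0], "b")
        r1 = ev.compare_groups(a, b, "area_mm2")
        r2 = ev.compare_groups(b, a, "area_mm2")
        assert r1.t == pytest.approx(-r2.t)
        assert r1.p == pytest.approx(r2.p)

    def test_insufficient_replicates_rejected(self):
        a = self._summaries([1.0], "a")
        b = self._summaries([1.0, 2.0], "b")
        with pytest.raises(AnalysisError):
            ev.compare_groups(a, b, "duration_min")

    def test_unknown_parameter_rejected(self):
        a = self._summaries([1.0, 2.0], "a")
        with pytest.raises(ConfigError):
            ev.compare_groups(a, a, "bogus")
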