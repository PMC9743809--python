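"""I-VT detection, capture rate, pupil baseline, interval metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cogload.errors import (
    ConfigurationError,
    InsufficientDataError,
    InvalidInputError,
)
from cogload.eye import (
    EyeEvent,
    PupilBaseline,
    astigmatism_covariate,
    capture_rate,
    filter_participants,
    interval_metrics,
    ivt_detect,
    pupil_baseline,
)

FS = 60.0


def _stream(ts, x, y, pupil=3.0, valid=True):
    n = len(ts)
    as_arr = lambda v: np.full(n, v) if np.isscalar(v) else np.asarray(v)
    return pd.DataFrame(
        {
            "ts": ts,
            "gaze_x": as_arr(x),
            "gaze_y": as_arr(y),
            "pupil_left": as_arr(pupil),
            "pupil_right": as_arr(pupil),
            "valid_left": as_arr(valid).astype(bool),
            "valid_right": as_arr(valid).astype(bool),
        }
    )


class TestIvtDetect:
    def test_stationary_gaze_is_one_fixation_of_about_1s(self):
        ts = np.arange(60) / FS
        events = ivt_detect(_stream(ts, 1.0, 1.0), degrees_per_unit=1.0)
        assert len(events) == 1
        assert events[0].kind == "fixation"
        assert events[0].duration_ms == pytest.approx(1000.0, abs=40)

    def test_jump_between_two_fixations(self):
        ts = np.arange(120) / FS
        x = np.where(ts < 1.0, 0.0, 10.0)  # 10 deg jump in one sample
        events = ivt_detect(_stream(ts, x, 0.0), degrees_per_unit=1.0)
        kinds = [e.kind for e in events]
        assert kinds == ["fixation", "saccade", "fixation"]

    def test_all_invalid_stream_yields_no_events(self):
        ts = np.arange(30) / FS
        events = ivt_detect(_stream(ts, 0.0, 0.0, valid=False),
                            degrees_per_unit=1.0)
        assert events == []

    def test_short_fixation_discarded(self):
        ts = np.arange(120) / FS
        # 2-sample dwell (33 ms < 60 ms minimum) between two long dwells
        x = np.zeros(120)
        x[60:62] = 5.0
        x[62:] = 10.0
        events = ivt_detect(_stream(ts, x, 0.0), degrees_per_unit=1.0)
        fix_durs = [e.duration_ms for e in events if e.kind == "fixation"]
        assert all(d >= 60.0 for d in fix_durs)

    def test_missing_geometry_rejected(self):
        ts = np.arange(30) / FS
        with pytest.raises(ConfigurationError):
            ivt_detect(_stream(ts, 0.0, 0.0))


class TestCaptureRate:
    def test_all_valid(self):
        ts = np.arange(10) / FS
        assert capture_rate(_stream(ts, 0, 0)).fraction == 1.0

    def test_half_valid(self):
        ts = np.arange(10) / FS
        valid = np.arange(10) % 2 == 0
        assert capture_rate(_stream(ts, 0, 0, valid=valid)).fraction == 0.5

    def test_empty_stream_rejected(self):
        with pytest.raises(InsufficientDataError):
            capture_rate(_stream(np.array([]), 0, 0))

    def test_simulated_missingness_recovers_rate(self, rng):
        from cogload.simulate import GazeSimConfig, simulate_session

        b = simulate_session(
            103, seed=9, include_eeg=False, missing_prob=0.3,
        )
        rate = capture_rate(b.gaze).fraction
        n = len(b.gaze)
        se = np.sqrt(0.3 * 0.7 / n)
        assert rate == pytest.approx(0.7, abs=4 * se)


class TestPupilBaseline:
    def test_constant_rest(self):
        ts = np.arange(600) / FS
        base = pupil_baseline(_stream(ts, 0, 0, pupil=3.0), (0.0, 10.0))
        assert base.left == pytest.approx(3.0)
        assert base.right == pytest.approx(3.0)

    def test_mean_of_rest_samples(self):
        ts = np.arange(20) / FS
        pupil = np.tile([2.9, 3.1], 10)
        base = pupil_baseline(_stream(ts, 0, 0, pupil=pupil), (0.0, 1.0))
        assert base.left == pytest.approx(3.0)

    def test_invalid_rest_rejected(self):
        ts = np.arange(600) / FS
        with pytest.raises(InsufficientDataError):
            pupil_baseline(_stream(ts, 0, 0, valid=False), (0.0, 10.0))


class TestIntervalMetrics:
    @staticmethod
    def _baseline():
        return PupilBaseline(3.0, 3.0, (0.0, 10.0), 100, 100)

    def test_pupil_at_baseline_gives_zero_dilation(self):
        ts = np.arange(60) / FS
        m = interval_metrics(_stream(ts, 0, 0, pupil=3.0), [], (0.0, 1.0),
                             self._baseline())
        assert m.avg_pupil_dilation_left == pytest.approx(0.0)
        assert m.max_pupil_dilation_left == pytest.approx(0.0)

    def test_avg_and_max_dilation(self):
        ts = np.array([0.0, 0.5])
        pupil = np.array([3.1, 2.9])
        m = interval_metrics(_stream(ts, 0, 0, pupil=pupil), [], (0.0, 1.0),
                             self._baseline())
        assert m.avg_pupil_dilation_left == pytest.approx(0.0)
        assert m.max_pupil_dilation_left == pytest.approx(0.1)

    def test_fixation_rate_counts_starts_in_interval(self):
        ts = np.arange(60) / FS
        events = [
            EyeEvent("fixation", 0.1, 0.3),
            EyeEvent("fixation", 0.4, 0.6),
            EyeEvent("fixation", 0.7, 0.9),
            EyeEvent("fixation", 1.5, 1.7),  # starts outside
        ]
        m = interval_metrics(_stream(ts, 0, 0), events, (0.0, 1.0),
                             self._baseline())
        assert m.fixation_number_per_second == pytest.approx(3.0)
        assert m.n_fixations == 3

    def test_max_at_least_avg(self):
        ts = np.arange(60) / FS
        events = [
            EyeEvent("fixation", 0.0, 0.2),
            EyeEvent("saccade", 0.2, 0.25),
            EyeEvent("fixation", 0.25, 0.8),
        ]
        m = interval_metrics(_stream(ts, 0, 0), events, (0.0, 1.0),
                             self._baseline())
        assert m.max_fixation_duration_ms >= m.avg_fixation_duration_ms

    def test_no_events_flagged_not_zero(self):
        ts = np.arange(60) / FS
        m = interval_metrics(_stream(ts, 0, 0), [], (0.0, 1.0), self._baseline())
        assert m.avg_fixation_duration_ms is None
        assert "no_fixations" in m.flags
        assert m.fixation_number_per_second == 0.0

    @given(c=st.floats(min_value=-2.0, max_value=2.0))
    def test_dilation_translation_equivariance(self, c):
        ts = np.arange(30) / FS
        pupil = 3.0 + 0.1 * np.sin(ts)
        base = self._baseline()
        shifted = PupilBaseline(base.left + c, base.right + c, base.window,
                                base.n_left, base.n_right)
        m0 = interval_metrics(_stream(ts, 0, 0, pupil=pupil), [], (0.0, 0.5), base)
        m1 = interval_metrics(_stream(ts, 0, 0, pupil=pupil + c), [], (0.0, 0.5),
                              shifted)
        assert m1.avg_pupil_dilation_left == pytest.approx(
            m0.avg_pupil_dilation_left, abs=1e-9
        )
        assert m1.max_pupil_dilation_left == pytest.approx(
            m0.max_pupil_dilation_left, abs=1e-9
        )


class TestScreening:
    def test_threshold_filters(self):
        included, report = filter_participants({1: 0.9, 2: 0.1}, 0.6)
        assert included == {1}
        assert len(report) == 2
        assert (report["min_rate"] == 0.6).all()

    def test_zero_threshold_includes_all(self):
        included, _ = filter_participants({1: 0.9, 2: 0.0}, 0.0)
        assert included == {1, 2}

    def test_reproducible_under_fixed_seed(self):
        from cogload.simulate import simulate_cohort

        def run():
            bundles = simulate_cohort(8, seed=3, include_eeg=False)
            rates = {b.participant_id: b.truth.capture_rate for b in bundles}
            return filter_participants(rates, 0.6)[0]

        assert run() == run()


class TestAstigmatism:
    @pytest.mark.parametrize(
        "l,r,expected", [(500, 600, 550), (0, 0, 0), (100, 300, 200)]
    )
    def test_mean_of_two_eyes(self, l, r, expected):
        assert astigmatism_covariate(l, r) == expected

    def test_negative_rejected(self):
        with pytest.raises(InvalidInputError):
            astigmatism_covariate(-1, 100)
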