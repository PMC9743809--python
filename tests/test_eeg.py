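"""Band filtering, power, segmentation, and the ERD/ERS computation."""

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from cogload.eeg import (
    CHANNELS,
    BandDef,
    EEGRecording,
    Interval,
    bandpass,
    condition_means,
    erd,
    erd_table,
    mean_power,
    power_samples,
    segment,
)
from cogload.errors import (
    ConfigurationError,
    InsufficientDataError,
    IntegrityError,
    InvalidInputError,
    UndefinedBaselineError,
)
from cogload.task import TrialRecord

FS = 256.0
ALPHA = BandDef("Alpha", 8.0, 13.0)
BETA = BandDef("Beta", 13.0, 30.0)


def _recording(x, fs=FS, start=0.0):
    return EEGRecording(np.tile(x, (4, 1)), CHANNELS, fs, start)


def _sinusoid(freq, duration=8.0, amplitude=1.0, fs=FS):
    t = np.arange(int(duration * fs)) / fs
    return amplitude * np.sin(2 * np.pi * freq * t)


class TestBandpass:
    def test_in_band_tone_preserved(self):
        rec = bandpass(_recording(_sinusoid(10.0)), ALPHA)
        core = rec.data[0][512:-512]  # avoid recording-edge transients
        rms = np.sqrt(np.mean(core**2))
        assert rms == pytest.approx(1 / np.sqrt(2), rel=0.05)

    def test_out_of_band_tone_attenuated(self):
        rec = bandpass(_recording(_sinusoid(10.0)), BETA)
        core = rec.data[0][512:-512]
        rms = np.sqrt(np.mean(core**2))
        assert rms < (1 / np.sqrt(2)) / 10

    def test_zero_signal_passes_through(self):
        rec = bandpass(_recording(np.zeros(1024)), ALPHA)
        assert np.allclose(rec.data, 0.0)

    def test_band_above_nyquist_rejected(self):
        with pytest.raises(ConfigurationError):
            bandpass(_recording(np.zeros(1024)), BandDef("X", 100.0, 200.0))


class TestPowerSamples:
    def test_constant_amplitude_squares(self):
        p = power_samples(_recording(np.full(100, 2.0)))
        assert np.allclose(p, 4.0)

    def test_sinusoid_mean_power(self):
        p = power_samples(_recording(_sinusoid(10.0, amplitude=3.0)))
        assert p.mean() == pytest.approx(9.0 / 2, rel=1e-3)

    def test_empty_channel(self):
        p = power_samples(_recording(np.empty(0)))
        assert p.shape == (4, 0)


def _trial(i, onset, rt, pid=1, cond="low", n=1):
    response = None if rt is None else onset + rt
    correct = None if i < n else (rt is not None)
    choice = "none" if rt is None or i < n else "match"
    return TrialRecord(pid, cond, n, i, "A", onset, response, choice, correct)


class TestSegment:
    def test_counts_for_answered_trials(self):
        trials = [_trial(i, 20.0 + 4.0 * i, 1.5) for i in range(21)]
        ivs = segment(trials, rest_start_ts=0.0)
        assert sum(iv.kind == "activation" for iv in ivs) == 20
        assert sum(iv.kind == "baseline_near" for iv in ivs) == 20
        assert sum(iv.kind == "baseline_away" for iv in ivs) == 1

    def test_near_baseline_is_200ms(self):
        trials = [_trial(i, 20.0 + 4.0 * i, 1.0) for i in range(3)]
        ivs = segment(trials, 0.0)
        for iv in ivs:
            if iv.kind == "baseline_near":
                assert iv.duration_s == pytest.approx(0.2)

    def test_away_baseline_is_3s_at_rest_start(self):
        ivs = segment([_trial(i, 20.0 + 4.0 * i, 1.0) for i in range(2)], 5.0)
        away = [iv for iv in ivs if iv.kind == "baseline_away"][0]
        assert away.start_ts == 5.0
        assert away.duration_s == pytest.approx(3.0)

    def test_timeout_trial_gets_full_window_flagged(self):
        trials = [_trial(0, 16.0, 1.0), _trial(1, 20.0, None)]
        ivs = segment(trials, 0.0)
        act = [iv for iv in ivs if iv.kind == "activation"
               and iv.trial_index == 1][0]
        assert act.duration_s == pytest.approx(3.0)
        assert "timeout" in act.flags

    def test_response_before_onset_rejected(self):
        bad = TrialRecord(1, "low", 1, 1, "A", 20.0, 19.5, "match", True)
        with pytest.raises(IntegrityError):
            segment([_trial(0, 16.0, 1.0), bad], 0.0)

    def test_clipping_flagged(self):
        trials = [_trial(i, 1.0 + 4.0 * i, 2.0) for i in range(3)]
        # span starts inside the first scoreable trial's near baseline
        ivs = segment(trials, 0.0, span=(4.9, 50.0))
        near_first = [iv for iv in ivs if iv.kind == "baseline_near"
                      and iv.trial_index == 1][0]
        assert "clipped" in near_first.flags
        assert near_first.start_ts == pytest.approx(4.9)


class TestMeanPower:
    def test_constant_power(self):
        times = np.arange(10, dtype=float)
        value, n = mean_power(np.full(10, 4.0), times, Interval(2.0, 6.0, "activation"))
        assert value == 4.0
        assert n == 4

    def test_two_sample_average(self):
        value, _ = mean_power(
            np.array([2.0, 6.0]), np.array([0.0, 1.0]), Interval(0.0, 2.0, "activation")
        )
        assert value == 4.0

    def test_interval_outside_recording(self):
        with pytest.raises(InsufficientDataError):
            mean_power(np.ones(5), np.arange(5.0), Interval(10.0, 12.0, "activation"))


class TestErd:
    @pytest.mark.parametrize(
        "R,A,fraction", [(2.0, 1.0, 0.5), (3.0, 3.0, 0.0), (1.0, 0.0, 1.0), (1.0, 2.0, -1.0)]
    )
    def test_direct_identities(self, R, A, fraction):
        r = erd(R, A)
        assert r.value_fraction == pytest.approx(fraction)
        assert r.value_percent == pytest.approx(100 * fraction)

    @given(
        R=st.floats(min_value=1e-6, max_value=1e6),
        A=st.floats(min_value=0.0, max_value=1e6),
        c=st.floats(min_value=1e-6, max_value=1e6),
    )
    def test_scale_invariance(self, R, A, c):
        assert erd(c * R, c * A).value_fraction == pytest.approx(
            erd(R, A).value_fraction, rel=1e-9, abs=1e-9
        )

    def test_monotone_decreasing_in_activation_power(self):
        values = [erd(2.0, a).value_fraction for a in np.linspace(0, 4, 9)]
        assert all(b < a for a, b in zip(values, values[1:]))

    def test_zero_reference_rejected(self):
        with pytest.raises(UndefinedBaselineError):
            erd(0.0, 1.0)

    def test_negative_activation_rejected(self):
        with pytest.raises(InvalidInputError):
            erd(1.0, -0.5)


def _oracle_recording(d, n_trials=10, fs=FS):
    """Noiseless 10 Hz tone; amplitude x sqrt(1-d) inside activations."""
    onsets = 12.0 + 4.5 * np.arange(n_trials)
    duration = onsets[-1] + 6.0
    t = np.arange(int(duration * fs)) / fs
    env = np.ones_like(t)
    for o in onsets:
        i0, i1 = int(np.ceil(o * fs)), int(np.ceil((o + 3.0) * fs))
        env[i0:i1] = np.sqrt(1 - d)
    rec = _recording(env * np.sin(2 * np.pi * 10.0 * t))
    trials = [_trial(i + 1, o, 3.0) for i, o in enumerate(onsets)]
    return rec, trials


class TestErdTable:
    def test_structure_and_trial_conservation(self):
        rec, trials = _oracle_recording(0.3)
        table, exclusions = erd_table(
            rec, trials, 0.0, bands=(ALPHA,), channels=("AF7",)
        )
        included = len(table)
        excluded = sum(exclusions.values())
        answered = sum(1 for t in trials if t.correct is not None)
        assert included + excluded == answered

    def test_oracle_equivalence_away_baseline(self):
        # single clean 3 s reference: pipeline recovers the injected
        # power fraction almost exactly
        rec, trials = _oracle_recording(0.4)
        table, _ = erd_table(
            rec, trials, 0.0, bands=(ALPHA,), channels=("AF7",),
            baseline_mode="away",
        )
        assert table["value_fraction"].mean() == pytest.approx(0.4, abs=0.02)

    def test_near_and_away_agree_on_effect_sign(self):
        rec, trials = _oracle_recording(0.4)
        near, _ = erd_table(rec, trials, 0.0, bands=(ALPHA,),
                            channels=("AF7",), baseline_mode="near")
        away, _ = erd_table(rec, trials, 0.0, bands=(ALPHA,),
                            channels=("AF7",), baseline_mode="away")
        assert np.sign(near["value_fraction"].mean()) == np.sign(
            away["value_fraction"].mean()
        )

    def test_condition_means_grouping(self):
        rec, trials = _oracle_recording(0.2)
        table, _ = erd_table(rec, trials, 0.0, bands=(ALPHA,), channels=("AF7",))
        means = condition_means(table)
        assert set(means.columns) >= {"measure", "block_label", "mean", "n"}
        assert means["n"].sum() == len(table)

    def test_no_valid_trials_raises(self):
        rec, _ = _oracle_recording(0.0, n_trials=2)
        far = [_trial(1, 1e6, 1.0)]
        with pytest.raises(InsufficientDataError):
            erd_table(rec, far, 1e6 - 12.0, bands=(ALPHA,), channels=("AF7",))
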