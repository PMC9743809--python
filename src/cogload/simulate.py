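"""Synthetic N-back sessions with known ground truth.

Every downstream stage (behavioral scoring, EEG ERD/ERS, eye metrics,
rank statistics) is testable against effects injected here:

* **Behavior** — lognormal reaction times and Bernoulli accuracy per
  condition; responses slower than the stimulus timeout become
  timeouts.  Defaults match the reference protocol's observed scale
  (RT medians ≈ 1.06 / 1.43 s, accuracy 0.94 / 0.85).
* **EEG** — stationary band-limited oscillations (Theta/Alpha/Beta
  sinusoids) over 1/f background noise, four channels at 256 Hz.  A
  fractional band-power change ``d`` per (band, channel, condition) is
  injected by scaling the band component's *amplitude* by ``sqrt(1-d)``
  inside each activation interval, so mean band power drops by exactly
  the fraction ``d`` (negative ``d`` = power increase, the direction
  consumer-headband N-back studies report for Alpha/Beta).
* **Gaze** — alternating lognormal fixations and saccades at 60 Hz;
  pupil = per-participant baseline + condition shift + slow drift +
  sample noise; samples are dropped i.i.d. at a per-participant missing
  probability.  Across a cohort, astigmatism degree and missing
  probability are coupled through a Gaussian copula whose strength is
  parameterized directly by the target population Spearman correlation
  between astigmatism and capture rate (via r = 2·sin(π·ρ/6)).

Session timeline: 10 s eyes-open rest → first block → 5 s rest →
second block, with block order counterbalanced by participant-ID
parity.  All generation is deterministic given the seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from . import task as task_mod
from .eeg import CHANNELS, EEGRecording, Interval
from .errors import ConfigurationError, InvalidInputError, TimelineError
from .eye import GAZE_COLUMNS, EyeEvent
from .task import (
    CONDITION_N_LEVEL,
    HIGH_WORKLOAD_LETTERS,
    LOW_WORKLOAD_LETTERS,
    TaskConfig,
    TrialRecord,
    assign_orders,
    derive_response_key,
)

__all__ = [
    "EEGSimConfig",
    "GazeSimConfig",
    "BehaviorSimConfig",
    "GroundTruth",
    "SessionBundle",
    "simulate_session",
    "simulate_cohort",
    "astigmatism_capture_sample",
    "sample_interval_dilations",
    "DEFAULT_ERD_TRUTH",
]

CONDITIONS = ("low", "high")

#: Default injected fractional band-power changes per
#: (band, channel, condition), on the scale consumer-headband N-back
#: recordings exhibit: Theta power drops a little during activation
#: (positive d), Alpha and Beta power rise (negative d), with slightly
#: larger magnitudes in the high-workload condition.
DEFAULT_ERD_TRUTH: dict[tuple[str, str, str], float] = {
    ("Theta", "TP9", "low"): 0.16, ("Theta", "TP9", "high"): 0.20,
    ("Theta", "AF7", "low"): 0.33, ("Theta", "AF7", "high"): 0.40,
    ("Theta", "AF8", "low"): 0.50, ("Theta", "AF8", "high"): 0.50,
    ("Theta", "TP10", "low"): 0.11, ("Theta", "TP10", "high"): 0.14,
    ("Alpha", "TP9", "low"): -0.07, ("Alpha", "TP9", "high"): -0.10,
    ("Alpha", "AF7", "low"): -0.12, ("Alpha", "AF7", "high"): -0.17,
    ("Alpha", "AF8", "low"): -0.19, ("Alpha", "AF8", "high"): -0.21,
    ("Alpha", "TP10", "low"): -0.07, ("Alpha", "TP10", "high"): -0.08,
    ("Beta", "TP9", "low"): -0.05, ("Beta", "TP9", "high"): -0.065,
    ("Beta", "AF7", "low"): -0.08, ("Beta", "AF7", "high"): -0.083,
    ("Beta", "AF8", "low"): -0.08, ("Beta", "AF8", "high"): -0.105,
    ("Beta", "TP10", "low"): -0.074, ("Beta", "TP10", "high"): -0.080,
}


@dataclass(frozen=True)
class EEGSimConfig:
    """Oscillation + 1/f-noise EEG generator settings."""

    sampling_rate: float = 256.0
    channels: tuple[str, ...] = CHANNELS
    band_amplitudes: Mapping[str, float] = field(
        default_factory=lambda: {"Theta": 8.0, "Alpha": 15.0, "Beta": 6.0}
    )  # µV at rest
    band_freqs: Mapping[str, float] = field(
        default_factory=lambda: {"Theta": 6.0, "Alpha": 10.0, "Beta": 20.0}
    )  # Hz, one carrier per band
    erd_truth: Mapping[tuple[str, str, str], float] = field(
        default_factory=lambda: dict(DEFAULT_ERD_TRUTH)
    )
    noise_exponent: float = 1.0  # 1/f^exponent background
    noise_amplitude: float = 2.0  # µV RMS
    line_noise_hz: Optional[float] = None  # 50, 60 or None
    line_noise_amplitude: float = 2.0  # µV

    def __post_init__(self) -> None:
        top = max(self.band_freqs.values())
        if self.sampling_rate <= 2 * top:
            raise ConfigurationError("sampling_rate must exceed twice the top band")
        if any(d >= 1.0 for d in self.erd_truth.values()):
            raise ConfigurationError("fractional power change d must be < 1")


@dataclass(frozen=True)
class GazeSimConfig:
    """Fixation/saccade stream and pupillometry generator settings."""

    sampling_rate: float = 60.0
    # lognormal (log-median-seconds, sigma) per condition; "rest" covers
    # the pre/inter-block periods
    fixation_duration: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "low": (math.log(0.170), 0.55),
            "high": (math.log(0.170), 0.55),
            "rest": (math.log(0.250), 0.55),
        }
    )
    saccade_duration: tuple[float, float] = (math.log(0.025), 0.25)
    pupil_baseline_mm: float = 3.5
    pupil_shift_mm: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.11, "high": 0.20}
    )
    pupil_noise_sd_mm: float = 0.08  # white, per sample
    pupil_slow_sd_mm: float = 0.30  # slow drift (≈5 s timescale)
    pupil_slow_window_s: float = 5.0
    missing_prob: float = 0.10  # i.i.d. per sample, both eyes together
    screen_halfwidth_deg: float = 8.0
    fixation_jitter_deg: float = 0.05

    def __post_init__(self) -> None:
        if not 0.0 <= self.missing_prob <= 1.0:
            raise ConfigurationError("missing_prob must lie in [0, 1]")


@dataclass(frozen=True)
class BehaviorSimConfig:
    """Reaction-time and accuracy generator settings.

    RT is lognormal per condition with parameters (µ, σ) on the log
    scale, back-solved from the reference medians/means
    (low: median 1.06 s, mean 1.11 s; high: median 1.43 s, mean 1.58 s).
    """

    rt_lognormal: Mapping[str, tuple[float, float]] = field(
        default_factory=lambda: {"low": (0.0583, 0.304), "high": (0.3577, 0.447)}
    )
    accuracy_p: Mapping[str, float] = field(
        default_factory=lambda: {"low": 0.94, "high": 0.85}
    )

    def __post_init__(self) -> None:
        for cond, p in self.accuracy_p.items():
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"accuracy_p[{cond!r}] must lie in [0, 1]")
        for cond, (_, sigma) in self.rt_lognormal.items():
            if sigma <= 0:
                raise ConfigurationError(f"rt sigma for {cond!r} must be > 0")


@dataclass(frozen=True)
class GroundTruth:
    """Injected simulation parameters, recorded before any realization."""

    participant_id: int
    order: str
    erd_truth: dict[tuple[str, str, str], float]
    pupil_shift_mm: dict[str, float]
    rt_lognormal: dict[str, tuple[float, float]]
    accuracy_p: dict[str, float]
    astigmatism_deg: float
    missing_prob: float
    capture_rate: Optional[float]  # realized, filled after gaze generation
    seed: int


@dataclass
class SessionBundle:
    """One participant's synthetic session: behavior + EEG + gaze + truth."""

    participant_id: int
    order: str
    task_config: TaskConfig
    trials: Optional[list[TrialRecord]]
    recording: Optional[EEGRecording]
    gaze: Optional[pd.DataFrame]
    events: Optional[list[EyeEvent]]
    rest_interval: tuple[float, float]
    block_spans: dict[str, tuple[float, float]]
    truth: GroundTruth
    dropped: bool = False


def _block_letters(condition: str) -> str:
    return LOW_WORKLOAD_LETTERS if condition == "low" else HIGH_WORKLOAD_LETTERS


def _simulate_trials(
    participant_id: int,
    order: str,
    start_ts: float,
    task_cfg: TaskConfig,
    behav: BehaviorSimConfig,
    rng: np.random.Generator,
) -> tuple[list[TrialRecord], dict[str, tuple[float, float]], float]:
    """Roll the behavioral timeline; returns (trials, block spans, end time)."""
    conditions = ("low", "high") if order == "Order1" else ("high", "low")
    timeout = task_cfg.stimulus_timeout_s
    iti_lo, iti_hi = task_cfg.inter_stimulus_interval_s
    t = start_ts + task_cfg.rest_eyes_open_s
    trials: list[TrialRecord] = []
    spans: dict[str, tuple[float, float]] = {}
    for b, cond in enumerate(conditions):
        n = CONDITION_N_LEVEL[cond]
        letters = _block_letters(cond)
        key = str(derive_response_key(letters, n))
        block_start = t
        for i, letter in enumerate(letters):
            onset = t
            if i < n:  # unscoreable lead-in: displayed for the full timeout
                response = None
                choice = "none"
                correct = None
                display = timeout
            else:
                mu, sigma = behav.rt_lognormal[cond]
                rt = float(rng.lognormal(mu, sigma))
                if rt >= timeout:
                    response, choice, correct = None, "none", False
                    display = timeout
                else:
                    response = onset + rt
                    correct = bool(rng.random() < behav.accuracy_p[cond])
                    truth_choice = "match" if key[i - n] == "Y" else "nonmatch"
                    wrong = "nonmatch" if truth_choice == "match" else "match"
                    choice = truth_choice if correct else wrong
                    display = rt
            trials.append(
                TrialRecord(
                    participant_id=participant_id,
                    block_label=cond,
                    n_level=n,
                    trial_index=i,
                    letter=letter,
                    onset_ts=onset,
                    response_ts=response,
                    choice=choice,
                    correct=correct,
                )
            )
            t = onset + display + float(rng.uniform(iti_lo, iti_hi))
        spans[cond] = (block_start, t)
        if b == 0:
            t += task_cfg.rest_between_blocks_s
    return trials, spans, t


def _pink_noise(
    n: int, exponent: float, rng: np.random.Generator
) -> np.ndarray:
    """Unit-variance 1/f^exponent noise via spectral shaping."""
    freqs = np.fft.rfftfreq(n, d=1.0)
    shape = np.zeros_like(freqs)
    shape[1:] = freqs[1:] ** (-exponent / 2.0)
    spectrum = shape * (
        rng.standard_normal(len(freqs)) + 1j * rng.standard_normal(len(freqs))
    )
    x = np.fft.irfft(spectrum, n=n)
    sd = x.std()
    return x / sd if sd > 0 else x


def _generate_eeg(
    start_ts: float,
    duration_s: float,
    cfg: EEGSimConfig,
    activation: Mapping[str, Sequence[tuple[float, float]]],
    rng: np.random.Generator,
) -> EEGRecording:
    fs = cfg.sampling_rate
    n = int(round(duration_s * fs))
    t = np.arange(n) / fs
    data = np.zeros((len(cfg.channels), n))
    for ci, ch in enumerate(cfg.channels):
        x = cfg.noise_amplitude * _pink_noise(n, cfg.noise_exponent, rng)
        for band, amp in cfg.band_amplitudes.items():
            envelope = np.ones(n)
            for cond, windows in activation.items():
                d = cfg.erd_truth.get((band, ch, cond), 0.0)
                if d == 0.0:
                    continue
                factor = math.sqrt(1.0 - d)
                for w0, w1 in windows:
                    i0 = max(0, int(math.ceil((w0 - start_ts) * fs)))
                    i1 = min(n, int(math.ceil((w1 - start_ts) * fs)))
                    if i0 >= i1:
                        raise TimelineError(
                            "activation interval outside the recording"
                        )
                    envelope[i0:i1] = factor
            phase = rng.uniform(0.0, 2.0 * np.pi)
            x = x + amp * envelope * np.sin(
                2.0 * np.pi * cfg.band_freqs[band] * t + phase
            )
        if cfg.line_noise_hz is not None:
            x = x + cfg.line_noise_amplitude * np.sin(
                2.0 * np.pi * cfg.line_noise_hz * t + rng.uniform(0, 2 * np.pi)
            )
        data[ci] = x
    return EEGRecording(data, tuple(cfg.channels), fs, start_ts)


def _generate_gaze(
    start_ts: float,
    duration_s: float,
    cfg: GazeSimConfig,
    block_spans: Mapping[str, tuple[float, float]],
    missing_prob: float,
    rng: np.random.Generator,
) -> tuple[pd.DataFrame, list[EyeEvent]]:
    fs = cfg.sampling_rate
    n = int(round(duration_s * fs))
    ts = start_ts + np.arange(n) / fs

    def cond_at(t: float) -> str:
        for cond, (a, b) in block_spans.items():
            if a <= t < b:
                return cond
        return "rest"

    # alternating fixation/saccade events over the whole session
    events: list[EyeEvent] = []
    centers: list[tuple[float, float, float, float]] = []  # (t0, t1, x, y)
    t_cur = start_ts
    end_ts = start_ts + duration_s
    while t_cur < end_ts:
        mu, sigma = cfg.fixation_duration[cond_at(t_cur)]
        fix_dur = float(rng.lognormal(mu, sigma))
        fx = float(rng.uniform(-cfg.screen_halfwidth_deg, cfg.screen_halfwidth_deg))
        fy = float(rng.uniform(-cfg.screen_halfwidth_deg, cfg.screen_halfwidth_deg))
        t1 = min(t_cur + fix_dur, end_ts)
        events.append(EyeEvent("fixation", t_cur, t1))
        centers.append((t_cur, t1, fx, fy))
        t_cur = t1
        if t_cur >= end_ts:
            break
        mu_s, sigma_s = cfg.saccade_duration
        sac_dur = float(rng.lognormal(mu_s, sigma_s))
        t1 = min(t_cur + sac_dur, end_ts)
        events.append(EyeEvent("saccade", t_cur, t1))
        t_cur = t1

    # gaze position: piecewise-constant at fixation centers with jitter,
    # linear ramps during saccades
    gx = np.zeros(n)
    gy = np.zeros(n)
    c_ts = np.array([c[0] for c in centers])
    c_x = np.array([c[2] for c in centers])
    c_y = np.array([c[3] for c in centers])
    seg = np.clip(np.searchsorted(c_ts, ts, side="right") - 1, 0, len(centers) - 1)
    gx = c_x[seg] + rng.normal(0.0, cfg.fixation_jitter_deg, n)
    gy = c_y[seg] + rng.normal(0.0, cfg.fixation_jitter_deg, n)

    shift = np.zeros(n)
    for cond, (a, b) in block_spans.items():
        mask = (ts >= a) & (ts < b)
        shift[mask] = cfg.pupil_shift_mm.get(cond, 0.0)
    slow = np.zeros(n)
    if cfg.pupil_slow_sd_mm > 0:
        win = max(1, int(round(cfg.pupil_slow_window_s * fs)))
        raw = uniform_filter1d(rng.standard_normal(n), size=win, mode="reflect")
        sd = raw.std()
        if sd > 0:
            slow = cfg.pupil_slow_sd_mm * raw / sd
    noise_l = rng.normal(0.0, cfg.pupil_noise_sd_mm, n)
    noise_r = rng.normal(0.0, cfg.pupil_noise_sd_mm, n)
    # anisocoria: small constant left/right offset
    aniso = rng.normal(0.0, 0.05)
    pupil_l = cfg.pupil_baseline_mm + aniso + shift + slow + noise_l
    pupil_r = cfg.pupil_baseline_mm - aniso + shift + slow + noise_r

    valid = rng.random(n) >= missing_prob  # both eyes drop together
    pupil_l = np.where(valid, pupil_l, np.nan)
    pupil_r = np.where(valid, pupil_r, np.nan)
    gx = np.where(valid, gx, np.nan)
    gy = np.where(valid, gy, np.nan)

    stream = pd.DataFrame(
        {
            "ts": ts,
            "gaze_x": gx,
            "gaze_y": gy,
            "pupil_left": pupil_l,
            "pupil_right": pupil_r,
            "valid_left": valid,
            "valid_right": valid,
        },
        columns=list(GAZE_COLUMNS),
    )
    return stream, events


def simulate_session(
    participant_id: int,
    *,
    task_config: Optional[TaskConfig] = None,
    eeg_config: Optional[EEGSimConfig] = None,
    gaze_config: Optional[GazeSimConfig] = None,
    behavior_config: Optional[BehaviorSimConfig] = None,
    seed: int = 0,
    astigmatism_deg: Optional[float] = None,
    missing_prob: Optional[float] = None,
    include_eeg: bool = True,
    include_gaze: bool = True,
    start_ts: Optional[float] = None,
) -> SessionBundle:
    """Generate one participant's full session, deterministically.

    The participant's block order follows ID parity (odd → low block
    first).  ``astigmatism_deg`` and ``missing_prob`` default to an
    uncoupled draw/config value; :func:`simulate_cohort` supplies the
    copula-coupled values.
    """
    task_cfg = task_config or TaskConfig()
    eeg_cfg = eeg_config or EEGSimConfig()
    gaze_cfg = gaze_config or GazeSimConfig()
    behav_cfg = behavior_config or BehaviorSimConfig()
    rng = np.random.default_rng([seed, participant_id])
    order = assign_orders([participant_id])[participant_id]
    if start_ts is None:
        start_ts = 1_600_000_000.0 + 10_000.0 * participant_id
    if astigmatism_deg is None:
        astigmatism_deg = float(150.0 * np.exp(0.9 * rng.standard_normal()))
    if missing_prob is None:
        missing_prob = gaze_cfg.missing_prob

    trials, block_spans, t_end = _simulate_trials(
        participant_id, order, start_ts, task_cfg, behav_cfg, rng
    )
    duration = (t_end - start_ts) + 2.0  # small tail after the last trial

    activation: dict[str, list[tuple[float, float]]] = {c: [] for c in CONDITIONS}
    timeout = task_cfg.stimulus_timeout_s
    for tr in trials:
        if tr.correct is None:
            continue
        end = tr.response_ts if tr.response_ts is not None else tr.onset_ts + timeout
        activation[tr.block_label].append((tr.onset_ts, end))

    recording = (
        _generate_eeg(start_ts, duration, eeg_cfg, activation, rng)
        if include_eeg
        else None
    )
    gaze, events, capture = None, None, None
    if include_gaze:
        gaze, events = _generate_gaze(
            start_ts, duration, gaze_cfg, block_spans, missing_prob, rng
        )
        capture = float(gaze["valid_left"].mean())

    truth = GroundTruth(
        participant_id=participant_id,
        order=order,
        erd_truth=dict(eeg_cfg.erd_truth),
        pupil_shift_mm=dict(gaze_cfg.pupil_shift_mm),
        rt_lognormal=dict(behav_cfg.rt_lognormal),
        accuracy_p=dict(behav_cfg.accuracy_p),
        astigmatism_deg=astigmatism_deg,
        missing_prob=missing_prob,
        capture_rate=capture,
        seed=seed,
    )
    return SessionBundle(
        participant_id=participant_id,
        order=order,
        task_config=task_cfg,
        trials=trials,
        recording=recording,
        gaze=gaze,
        events=events,
        rest_interval=(start_ts, start_ts + task_cfg.rest_eyes_open_s),
        block_spans=block_spans,
        truth=truth,
    )


def _copula_correlation(target_spearman: float) -> float:
    """Gaussian-copula correlation realizing a target Spearman rho."""
    return 2.0 * math.sin(math.pi * target_spearman / 6.0)


def astigmatism_capture_sample(
    n: int,
    rng: np.random.Generator | int,
    *,
    target_spearman: float = -0.55,
    n_gaze_samples: int = 3000,
    missing_range: tuple[float, float] = (0.05, 0.80),
    astig_median: float = 150.0,
    astig_sigma: float = 0.9,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw coupled (astigmatism, missing_prob, realized capture rate).

    A Gaussian copula couples a lognormal astigmatism margin to a
    uniform missing-probability margin; because Spearman correlation is
    invariant under strictly monotone margins, the *population*
    Spearman between astigmatism and capture rate equals
    ``target_spearman`` exactly.  The realized capture rate adds
    binomial noise from ``n_gaze_samples`` validity draws.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    # capture = monotone decreasing in missing prob, so couple z2 to z1
    # with the OPPOSITE sign of the astigmatism->capture target
    r = _copula_correlation(-target_spearman)
    z1 = rng.standard_normal(n)
    z2 = r * z1 + math.sqrt(max(0.0, 1.0 - r * r)) * rng.standard_normal(n)
    astig = astig_median * np.exp(astig_sigma * z1)
    from scipy.stats import norm

    lo, hi = missing_range
    missing = lo + (hi - lo) * norm.cdf(z2)
    n_valid = rng.binomial(n_gaze_samples, 1.0 - missing)
    capture = n_valid / n_gaze_samples
    return astig, missing, capture


def sample_interval_dilations(
    n: int,
    median_mm: float,
    sd_mm: float,
    rng: np.random.Generator | int,
    *,
    contamination: float = 0.07,
    core_scale: float = 0.644,
    tail_scale: float = 2.96,
) -> np.ndarray:
    """Per-interval averaged pupil dilations at a given median and SD.

    Pupillometry interval averages are heavy-tailed: a small fraction
    of intervals is contaminated by blink recovery and tracking jitter.
    The model is a two-component contaminated normal centered at the
    median; ``core_scale`` and ``tail_scale`` are chosen so that the
    total SD equals ``sd_mm`` at the default contamination fraction
    ((1-c)·0.644² + c·2.96² ≈ 1).
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(int(rng))
    is_tail = rng.random(n) < contamination
    sd = np.where(is_tail, tail_scale * sd_mm, core_scale * sd_mm)
    return median_mm + sd * rng.standard_normal(n)


def simulate_cohort(
    n_participants: int = 30,
    *,
    seed: int = 0,
    ids: Optional[Sequence[int]] = None,
    dropout: frozenset[int] | set[int] = frozenset(),
    task_config: Optional[TaskConfig] = None,
    eeg_config: Optional[EEGSimConfig] = None,
    gaze_config: Optional[GazeSimConfig] = None,
    behavior_config: Optional[BehaviorSimConfig] = None,
    capture_spearman: float = -0.55,
    missing_range: tuple[float, float] = (0.05, 0.80),
    include_eeg: bool = True,
    include_gaze: bool = True,
) -> list[SessionBundle]:
    """Generate a counterbalanced cohort of synthetic sessions.

    IDs default to 101..100+n, so odd/even counterbalancing splits the
    cohort evenly.  ``dropout`` IDs yield bundles with no device
    streams (``dropped=True``), emulating participants whose recordings
    failed.  Astigmatism and gaze missingness are coupled across the
    cohort at the target population Spearman correlation.
    """
    if n_participants < 2:
        raise InvalidInputError("need at least 2 participants")
    if ids is None:
        ids = list(range(101, 101 + n_participants))
    elif len(ids) != n_participants:
        raise InvalidInputError("ids length must equal n_participants")
    cohort_rng = np.random.default_rng([seed, 999_983])
    astig, missing, _ = astigmatism_capture_sample(
        n_participants,
        cohort_rng,
        target_spearman=capture_spearman,
        missing_range=missing_range,
    )
    bundles: list[SessionBundle] = []
    for i, pid in enumerate(ids):
        if pid in dropout:
            task_cfg = task_config or TaskConfig()
            start = 1_600_000_000.0 + 10_000.0 * pid
            truth = GroundTruth(
                participant_id=pid,
                order=assign_orders([pid])[pid],
                erd_truth=dict((eeg_config or EEGSimConfig()).erd_truth),
                pupil_shift_mm=dict((gaze_config or GazeSimConfig()).pupil_shift_mm),
                rt_lognormal=dict(
                    (behavior_config or BehaviorSimConfig()).rt_lognormal
                ),
                accuracy_p=dict((behavior_config or BehaviorSimConfig()).accuracy_p),
                astigmatism_deg=float(astig[i]),
                missing_prob=float(missing[i]),
                capture_rate=None,
                seed=seed,
            )
            bundles.append(
                SessionBundle(
                    participant_id=pid,
                    order=truth.order,
                    task_config=task_cfg,
                    trials=None,
                    recording=None,
                    gaze=None,
                    events=None,
                    rest_interval=(start, start + task_cfg.rest_eyes_open_s),
                    block_spans={},
                    truth=truth,
                    dropped=True,
                )
            )
            continue
        bundles.append(
            simulate_session(
                pid,
                task_config=task_config,
                eeg_config=eeg_config,
                gaze_config=gaze_config,
                behavior_config=behavior_config,
                seed=seed,
                astigmatism_deg=float(astig[i]),
                missing_prob=float(missing[i]),
                include_eeg=include_eeg,
                include_gaze=include_gaze,
            )
        )
    return bundles
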