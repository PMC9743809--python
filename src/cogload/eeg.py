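"""Event-locked ERD/ERS computation from raw multichannel EEG.

Event-related desynchronization/synchronization quantifies the relative
change of band-limited EEG power between a reference (baseline) window
with mean power ``R`` and an activation window with mean power ``A``:

    ERD/ERS% = (R - A) / R * 100

Positive values mean the band power dropped during activation; negative
values mean it rose.  The quantification proceeds in four steps:
band-pass filter the signal, square the amplitude samples to obtain
power, average power within each window, and average across trials.

Two baseline strategies are supported:

* ``near`` — the 200 ms immediately preceding each letter onset (one
  reference per trial);
* ``away`` — a single 3 s window at the start of the eyes-open rest,
  shared by every trial of the session.

The activation window runs from letter onset to the response (at most
the stimulus timeout).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import signal as sps

from .errors import (
    ConfigurationError,
    InsufficientDataError,
    IntegrityError,
    InvalidInputError,
    UndefinedBaselineError,
)
from .task import TrialRecord

__all__ = [
    "CHANNELS",
    "BandDef",
    "DEFAULT_BANDS",
    "EEGRecording",
    "Interval",
    "ERDResult",
    "bandpass",
    "notch",
    "power_samples",
    "segment",
    "mean_power",
    "erd",
    "erd_table",
    "condition_means",
    "measure_name",
]

#: Electrode labels of the four-channel headband montage.
CHANNELS = ("TP9", "AF7", "AF8", "TP10")

SIGN_NOTE = (
    "positive = band power decreased during activation (desynchronization); "
    "negative = band power increased (synchronization)"
)


@dataclass(frozen=True)
class BandDef:
    """A frequency band [f_lo, f_hi) in Hz."""

    name: str
    f_lo: float
    f_hi: float

    def __post_init__(self) -> None:
        if not 0 < self.f_lo < self.f_hi:
            raise ConfigurationError(f"invalid band edges {self.f_lo}-{self.f_hi}")


#: Conventional band edges; the protocol leaves them open, so they are
#: configurable everywhere they are consumed.
DEFAULT_BANDS = (
    BandDef("Theta", 4.0, 8.0),
    BandDef("Alpha", 8.0, 13.0),
    BandDef("Beta", 13.0, 30.0),
)


@dataclass
class EEGRecording:
    """Fixed-rate multichannel EEG in microvolts.

    ``data`` has shape (n_channels, n_samples); sample ``i`` of every
    channel is timestamped ``start_ts + i / sampling_rate`` (Unix
    seconds).
    """

    data: np.ndarray
    channels: tuple[str, ...]
    sampling_rate: float
    start_ts: float

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[0] != len(self.channels):
            raise InvalidInputError("data must be (n_channels, n_samples)")
        if self.sampling_rate <= 0:
            raise InvalidInputError("sampling_rate must be positive")

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    @property
    def duration_s(self) -> float:
        return self.n_samples / self.sampling_rate

    def times(self) -> np.ndarray:
        """Unix timestamps of every sample."""
        return self.start_ts + np.arange(self.n_samples) / self.sampling_rate

    def channel(self, label: str) -> np.ndarray:
        try:
            return self.data[self.channels.index(label)]
        except ValueError:
            raise InvalidInputError(f"no channel {label!r}") from None


@dataclass(frozen=True)
class Interval:
    """A half-open time window [start_ts, end_ts) tagged with its role."""

    start_ts: float
    end_ts: float
    kind: str  # {"activation", "baseline_near", "baseline_away"}
    trial_index: Optional[int] = None
    block_label: Optional[str] = None
    flags: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if self.end_ts <= self.start_ts:
            raise InvalidInputError("interval end must be after start")

    @property
    def duration_s(self) -> float:
        return self.end_ts - self.start_ts


@dataclass(frozen=True)
class ERDResult:
    """ERD/ERS as a fraction and as a percentage."""

    value_fraction: float
    sign_note: str = SIGN_NOTE

    @property
    def value_percent(self) -> float:
        return 100.0 * self.value_fraction


def bandpass(recording: EEGRecording, band: BandDef, order: int = 4) -> EEGRecording:
    """Zero-phase Butterworth band-pass filter (applied forward-backward).

    Output has the same length and timestamps as the input.
    """
    nyq = recording.sampling_rate / 2.0
    if band.f_hi >= nyq:
        raise ConfigurationError(
            f"band edge {band.f_hi} Hz >= Nyquist {nyq} Hz"
        )
    sos = sps.butter(
        order, [band.f_lo, band.f_hi], btype="bandpass", fs=recording.sampling_rate,
        output="sos",
    )
    filtered = sps.sosfiltfilt(sos, recording.data, axis=1)
    return EEGRecording(
        filtered, recording.channels, recording.sampling_rate, recording.start_ts
    )


def notch(recording: EEGRecording, freq: float = 50.0, q: float = 30.0) -> EEGRecording:
    """Zero-phase notch filter for 50/60 Hz line noise."""
    if freq >= recording.sampling_rate / 2.0:
        raise ConfigurationError("notch frequency must be below Nyquist")
    b, a = sps.iirnotch(freq, q, fs=recording.sampling_rate)
    filtered = sps.filtfilt(b, a, recording.data, axis=1)
    return EEGRecording(
        filtered, recording.channels, recording.sampling_rate, recording.start_ts
    )


def power_samples(filtered: EEGRecording) -> np.ndarray:
    """Instantaneous power: elementwise square of the amplitude, µV²."""
    return np.square(filtered.data)


def segment(
    trials: Sequence[TrialRecord],
    rest_start_ts: float,
    *,
    near_window_s: float = 0.2,
    away_window_s: float = 3.0,
    timeout_s: float = 3.0,
    span: Optional[tuple[float, float]] = None,
) -> list[Interval]:
    """Build activation and baseline intervals from a behavioral log.

    Per scoreable trial: an activation interval from letter onset to the
    response (timeouts get the full ``timeout_s`` and a ``timeout``
    flag) and a ``near_window_s`` baseline ending at onset.  One
    ``away_window_s`` baseline starts at the eyes-open rest.  Intervals
    are clipped to ``span`` when given, with a ``clipped`` flag.
    """
    scoreable = [t for t in trials if t.correct is not None]
    onsets = [t.onset_ts for t in scoreable]
    if any(b <= a for a, b in zip(onsets, onsets[1:])):
        raise InvalidInputError("trial onsets must be strictly increasing")
    out: list[Interval] = []

    def _clip(start: float, end: float, kind: str, trial: Optional[TrialRecord],
              flags: tuple[str, ...]) -> None:
        if span is not None:
            lo, hi = span
            cs, ce = max(start, lo), min(end, hi)
            if cs != start or ce != end:
                if ce <= cs:
                    return  # entirely outside: dropped, caller counts exclusions
                flags = flags + ("clipped",)
                start, end = cs, ce
        out.append(
            Interval(
                start, end, kind,
                trial_index=None if trial is None else trial.trial_index,
                block_label=None if trial is None else trial.block_label,
                flags=flags,
            )
        )

    _clip(rest_start_ts, rest_start_ts + away_window_s, "baseline_away", None, ())
    for t in scoreable:
        if t.response_ts is not None:
            if t.response_ts <= t.onset_ts:
                raise IntegrityError(
                    f"trial {t.trial_index}: response before onset"
                )
            _clip(t.onset_ts, t.response_ts, "activation", t, ())
        else:
            _clip(t.onset_ts, t.onset_ts + timeout_s, "activation", t, ("timeout",))
        _clip(t.onset_ts - near_window_s, t.onset_ts, "baseline_near", t, ())
    return out


def mean_power(
    power: np.ndarray,
    times: np.ndarray,
    interval: Interval,
) -> tuple[float, int]:
    """Mean of power samples whose timestamps fall in [start, end).

    Returns ``(mean, n_samples_used)``; raises
    :class:`InsufficientDataError` when the interval contains no sample.
    """
    power = np.asarray(power, dtype=float)
    times = np.asarray(times, dtype=float)
    mask = (times >= interval.start_ts) & (times < interval.end_ts)
    n = int(mask.sum())
    if n == 0:
        raise InsufficientDataError(
            f"no samples in {interval.kind} interval "
            f"[{interval.start_ts:.3f}, {interval.end_ts:.3f})"
        )
    return float(power[mask].mean()), n


def erd(R: float, A: float) -> ERDResult:
    """ERD/ERS from reference power ``R`` and activation power ``A``.

    ``value_fraction = (R - A) / R``; multiply by 100 for the percent
    form.  ``R`` must be strictly positive.
    """
    if R <= 0:
        raise UndefinedBaselineError(f"reference power must be positive, got {R}")
    if A < 0:
        raise InvalidInputError(f"activation power must be nonnegative, got {A}")
    return ERDResult((R - A) / R)


def measure_name(band: str, channel: str, baseline_mode: str) -> str:
    """Conventional measure label, e.g. ``Alpha_ERD_AF7_near``.

    Theta is conventionally reported as ERS, Alpha/Beta as ERD.
    """
    kind = "ERS" if band == "Theta" else "ERD"
    return f"{band}_{kind}_{channel}_{baseline_mode}"


def erd_table(
    recording: EEGRecording,
    trials: Sequence[TrialRecord],
    rest_start_ts: float,
    *,
    bands: Sequence[BandDef] = DEFAULT_BANDS,
    channels: Optional[Sequence[str]] = None,
    baseline_mode: str = "near",
    near_window_s: float = 0.2,
    away_window_s: float = 3.0,
    timeout_s: float = 3.0,
    line_noise_hz: Optional[float] = None,
    filter_order: int = 4,
) -> tuple[pd.DataFrame, dict[str, int]]:
    """Per-trial, per-channel, per-band ERD/ERS for one session.

    Returns ``(table, exclusions)``.  The table has one row per
    (scoreable trial, channel, band) with columns ``trial_index``,
    ``block_label``, ``channel``, ``band``, ``measure``, ``R``, ``A``,
    ``n_ref``, ``n_act``, ``value_fraction``, ``value_percent``,
    ``flags``.  Trials whose reference or activation window yields no
    samples, or whose reference power is non-positive, are excluded and
    counted in ``exclusions`` (this is why Ns vary between analyses).
    """
    if baseline_mode not in ("near", "away"):
        raise ConfigurationError(f"unknown baseline_mode {baseline_mode!r}")
    if channels is None:
        channels = recording.channels
    rec = recording
    if line_noise_hz is not None:
        rec = notch(rec, line_noise_hz)
    times = rec.times()
    span = (times[0], times[-1] + 1.0 / rec.sampling_rate)
    intervals = segment(
        trials, rest_start_ts,
        near_window_s=near_window_s, away_window_s=away_window_s,
        timeout_s=timeout_s, span=span,
    )
    activations = {
        (iv.block_label, iv.trial_index): iv
        for iv in intervals
        if iv.kind == "activation"
    }
    near = {
        (iv.block_label, iv.trial_index): iv
        for iv in intervals
        if iv.kind == "baseline_near"
    }
    away = next((iv for iv in intervals if iv.kind == "baseline_away"), None)
    if baseline_mode == "away" and away is None:
        raise InsufficientDataError("away baseline lies outside the recording")

    rows: list[dict] = []
    exclusions = {"no_samples": 0, "nonpositive_reference": 0}
    for band in bands:
        filtered = bandpass(rec, band, order=filter_order)
        power = power_samples(filtered)
        ch_idx = {c: rec.channels.index(c) for c in channels}
        for trial_key, act_iv in activations.items():
            ref_iv = away if baseline_mode == "away" else near.get(trial_key)
            for ch, idx in ch_idx.items():
                try:
                    if ref_iv is None:
                        raise InsufficientDataError("missing reference interval")
                    R, n_ref = mean_power(power[idx], times, ref_iv)
                    A, n_act = mean_power(power[idx], times, act_iv)
                except InsufficientDataError:
                    exclusions["no_samples"] += 1
                    continue
                try:
                    result = erd(R, A)
                except UndefinedBaselineError:
                    exclusions["nonpositive_reference"] += 1
                    continue
                rows.append(
                    {
                        "trial_index": trial_key[1],
                        "block_label": act_iv.block_label,
                        "channel": ch,
                        "band": band.name,
                        "measure": measure_name(band.name, ch, baseline_mode),
                        "R": R,
                        "A": A,
                        "n_ref": n_ref,
                        "n_act": n_act,
                        "value_fraction": result.value_fraction,
                        "value_percent": result.value_percent,
                        "flags": ",".join(act_iv.flags),
                    }
                )
    if not rows:
        raise InsufficientDataError("no valid trials for any channel/band")
    return pd.DataFrame(rows), exclusions


def condition_means(table: pd.DataFrame) -> pd.DataFrame:
    """Average ERD/ERS per (measure, condition) over included trials."""
    grouped = (
        table.groupby(["measure", "block_label"])["value_fraction"]
        .agg(["mean", "median", "std", "count"])
        .reset_index()
        .rename(columns={"count": "n"})
    )
    return grouped
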