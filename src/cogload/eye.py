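"""Per-stimulus eye-movement and pupillometry workload metrics.

A gaze stream is a :class:`pandas.DataFrame` at a fixed sampling rate
with columns ``ts`` (Unix seconds), ``gaze_x``, ``gaze_y`` (screen
coordinates), ``pupil_left``, ``pupil_right`` (mm) and boolean
``valid_left``, ``valid_right`` flags.  Pupil *dilation* is diameter
minus a per-participant, per-eye baseline taken from the eyes-open rest.

Ten metrics are computed per stimulus interval (letter onset to
response): averaged/maximum pupil dilation per eye, averaged/maximum
fixation and saccade durations, and fixation/saccade counts per second.
Capture rate (fraction of valid samples) screens participants; it
degrades with astigmatism, which is summarized as the mean of the two
eyes' degrees.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .eeg import Interval
from .errors import ConfigurationError, InsufficientDataError, InvalidInputError

__all__ = [
    "GAZE_COLUMNS",
    "EyeEvent",
    "PupilBaseline",
    "IntervalEyeMetrics",
    "CaptureRate",
    "ivt_detect",
    "capture_rate",
    "pupil_baseline",
    "interval_metrics",
    "filter_participants",
    "astigmatism_covariate",
    "METRIC_FIELDS",
]

GAZE_COLUMNS = (
    "ts", "gaze_x", "gaze_y",
    "pupil_left", "pupil_right", "valid_left", "valid_right",
)

#: Metric field names in reporting order (mirrors the workload tables).
METRIC_FIELDS = (
    "avg_pupil_dilation_left",
    "avg_pupil_dilation_right",
    "max_pupil_dilation_left",
    "max_pupil_dilation_right",
    "avg_fixation_duration_ms",
    "fixation_number_per_second",
    "avg_saccade_duration_ms",
    "saccade_number_per_second",
    "max_fixation_duration_ms",
    "max_saccade_duration_ms",
)


@dataclass(frozen=True)
class EyeEvent:
    """A fixation or saccade as a half-open window [start_ts, end_ts)."""

    kind: str  # {"fixation", "saccade"}
    start_ts: float
    end_ts: float

    def __post_init__(self) -> None:
        if self.end_ts <= self.start_ts:
            raise InvalidInputError("event end must be after start")
        if self.kind not in ("fixation", "saccade"):
            raise InvalidInputError(f"unknown event kind {self.kind!r}")

    @property
    def duration_ms(self) -> float:
        return (self.end_ts - self.start_ts) * 1000.0


@dataclass(frozen=True)
class PupilBaseline:
    """Per-eye mean pupil diameter over valid rest samples, mm."""

    left: float
    right: float
    window: tuple[float, float]
    n_left: int
    n_right: int


@dataclass(frozen=True)
class CaptureRate:
    participant_id: Optional[int]
    fraction: float
    n_valid: int
    n_total: int


@dataclass(frozen=True)
class IntervalEyeMetrics:
    """Workload metrics for one stimulus interval.

    Metrics that cannot be computed (no valid samples, no events of a
    kind) are ``None`` and the reason appears in ``flags``; event rates
    with zero events are an honest 0.0.
    """

    interval: tuple[float, float]
    avg_pupil_dilation_left: Optional[float]
    avg_pupil_dilation_right: Optional[float]
    max_pupil_dilation_left: Optional[float]
    max_pupil_dilation_right: Optional[float]
    avg_fixation_duration_ms: Optional[float]
    max_fixation_duration_ms: Optional[float]
    fixation_number_per_second: float
    avg_saccade_duration_ms: Optional[float]
    max_saccade_duration_ms: Optional[float]
    saccade_number_per_second: float
    n_valid_samples: int
    n_fixations: int
    n_saccades: int
    flags: tuple[str, ...] = ()


def _check_stream(stream: pd.DataFrame) -> None:
    missing = [c for c in GAZE_COLUMNS if c not in stream.columns]
    if missing:
        raise InvalidInputError(f"gaze stream missing columns {missing}")


def ivt_detect(
    stream: pd.DataFrame,
    *,
    velocity_threshold_deg_s: float = 30.0,
    min_fixation_ms: float = 60.0,
    degrees_per_unit: Optional[float] = None,
) -> list[EyeEvent]:
    """Velocity-threshold (I-VT) fixation/saccade detection.

    Point-to-point gaze velocity below the threshold marks fixation
    samples, above marks saccade samples; contiguous runs become events.
    Below-threshold runs shorter than ``min_fixation_ms`` are discarded
    as unclassified.  Runs are broken at invalid samples.
    ``degrees_per_unit`` converts screen units to visual degrees and is
    required (pass 1.0 when coordinates are already degrees).
    """
    _check_stream(stream)
    if degrees_per_unit is None:
        raise ConfigurationError(
            "degrees_per_unit is required to express velocity in deg/s"
        )
    valid = (stream["valid_left"] & stream["valid_right"]).to_numpy(dtype=bool)
    ts = stream["ts"].to_numpy(dtype=float)
    if valid.sum() < 2:
        return []
    x = stream["gaze_x"].to_numpy(dtype=float) * degrees_per_unit
    y = stream["gaze_y"].to_numpy(dtype=float) * degrees_per_unit
    dt = float(np.median(np.diff(ts))) if len(ts) > 1 else 0.0

    events: list[EyeEvent] = []
    # split into runs of contiguous valid samples
    idx = np.flatnonzero(valid)
    breaks = np.flatnonzero(np.diff(idx) > 1)
    segments = np.split(idx, breaks + 1)
    for seg in segments:
        if len(seg) < 2:
            continue
        seg_ts, seg_x, seg_y = ts[seg], x[seg], y[seg]
        d = np.hypot(np.diff(seg_x), np.diff(seg_y))
        v = d / np.diff(seg_ts)
        v = np.concatenate([[v[0]], v])  # first sample inherits next velocity
        is_fix = v < velocity_threshold_deg_s
        change = np.flatnonzero(np.diff(is_fix.astype(int))) + 1
        bounds = np.concatenate([[0], change, [len(seg)]])
        for a, b in zip(bounds[:-1], bounds[1:]):
            start, end = seg_ts[a], seg_ts[b - 1] + dt
            if is_fix[a]:
                if (end - start) * 1000.0 >= min_fixation_ms:
                    events.append(EyeEvent("fixation", start, end))
            else:
                events.append(EyeEvent("saccade", start, end))
    return events


def capture_rate(
    stream: pd.DataFrame,
    participant_id: Optional[int] = None,
    *,
    policy: str = "both",
) -> CaptureRate:
    """Fraction of samples the tracker flagged valid.

    ``policy`` is ``"both"`` (both eyes valid; default), ``"left"``,
    ``"right"`` or ``"either"``.
    """
    _check_stream(stream)
    if len(stream) == 0:
        raise InsufficientDataError("empty gaze stream")
    left = stream["valid_left"].to_numpy(dtype=bool)
    right = stream["valid_right"].to_numpy(dtype=bool)
    if policy == "both":
        valid = left & right
    elif policy == "either":
        valid = left | right
    elif policy == "left":
        valid = left
    elif policy == "right":
        valid = right
    else:
        raise ConfigurationError(f"unknown validity policy {policy!r}")
    return CaptureRate(
        participant_id, float(valid.mean()), int(valid.sum()), len(valid)
    )


def pupil_baseline(
    stream: pd.DataFrame,
    rest: Interval | tuple[float, float],
    *,
    min_valid: int = 10,
) -> PupilBaseline:
    """Per-eye mean pupil diameter over valid samples in the rest window."""
    _check_stream(stream)
    start, end = (
        (rest.start_ts, rest.end_ts) if isinstance(rest, Interval) else rest
    )
    in_win = (stream["ts"] >= start) & (stream["ts"] < end)
    means = {}
    counts = {}
    for eye in ("left", "right"):
        mask = in_win & stream[f"valid_{eye}"].astype(bool)
        vals = stream.loc[mask, f"pupil_{eye}"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) < min_valid:
            raise InsufficientDataError(
                f"only {len(vals)} valid {eye}-eye rest samples (< {min_valid})"
            )
        means[eye] = float(vals.mean())
        counts[eye] = len(vals)
    return PupilBaseline(
        means["left"], means["right"], (start, end), counts["left"], counts["right"]
    )


def interval_metrics(
    stream: pd.DataFrame,
    events: Sequence[EyeEvent],
    interval: Interval | tuple[float, float],
    baseline: PupilBaseline,
) -> IntervalEyeMetrics:
    """The ten workload metrics for one stimulus interval.

    Pupil dilation = diameter − per-eye baseline, over valid samples in
    the interval.  Events are assigned to the interval by their start
    time; durations are not clipped.
    """
    _check_stream(stream)
    start, end = (
        (interval.start_ts, interval.end_ts)
        if isinstance(interval, Interval)
        else interval
    )
    if end <= start:
        raise InvalidInputError("interval end must be after start")
    length_s = end - start
    in_win = (stream["ts"] >= start) & (stream["ts"] < end)
    flags: list[str] = []

    pupil: dict[str, tuple[Optional[float], Optional[float]]] = {}
    n_valid = 0
    for eye, base in (("left", baseline.left), ("right", baseline.right)):
        mask = in_win & stream[f"valid_{eye}"].astype(bool)
        vals = stream.loc[mask, f"pupil_{eye}"].to_numpy(dtype=float)
        vals = vals[np.isfinite(vals)]
        if len(vals) == 0:
            pupil[eye] = (None, None)
            flags.append(f"no_valid_{eye}_samples")
        else:
            dil = vals - base
            pupil[eye] = (float(dil.mean()), float(dil.max()))
            n_valid = max(n_valid, len(vals))

    by_kind: dict[str, list[float]] = {"fixation": [], "saccade": []}
    for ev in events:
        if start <= ev.start_ts < end:
            by_kind[ev.kind].append(ev.duration_ms)
    durations = {}
    for kind in ("fixation", "saccade"):
        durs = by_kind[kind]
        if durs:
            durations[kind] = (float(np.mean(durs)), float(np.max(durs)))
        else:
            durations[kind] = (None, None)
            flags.append(f"no_{kind}s")

    return IntervalEyeMetrics(
        interval=(start, end),
        avg_pupil_dilation_left=pupil["left"][0],
        avg_pupil_dilation_right=pupil["right"][0],
        max_pupil_dilation_left=pupil["left"][1],
        max_pupil_dilation_right=pupil["right"][1],
        avg_fixation_duration_ms=durations["fixation"][0],
        max_fixation_duration_ms=durations["fixation"][1],
        fixation_number_per_second=len(by_kind["fixation"]) / length_s,
        avg_saccade_duration_ms=durations["saccade"][0],
        max_saccade_duration_ms=durations["saccade"][1],
        saccade_number_per_second=len(by_kind["saccade"]) / length_s,
        n_valid_samples=n_valid,
        n_fixations=len(by_kind["fixation"]),
        n_saccades=len(by_kind["saccade"]),
        flags=tuple(flags),
    )


def filter_participants(
    rates: Iterable[CaptureRate] | Mapping[int, float],
    min_rate: float = 0.6,
) -> tuple[set[int], pd.DataFrame]:
    """Screen participants by capture rate.

    Returns ``(included_ids, report)``; the report lists every
    participant with rate, threshold and decision.
    """
    if not 0.0 <= min_rate <= 1.0:
        raise InvalidInputError("min_rate must lie in [0, 1]")
    if isinstance(rates, Mapping):
        pairs = [(pid, float(r)) for pid, r in rates.items()]
    else:
        pairs = [(r.participant_id, r.fraction) for r in rates]
    report = pd.DataFrame(
        {
            "participant_id": [p for p, _ in pairs],
            "capture_rate": [r for _, r in pairs],
            "min_rate": min_rate,
        }
    )
    report["included"] = report["capture_rate"] >= min_rate
    included = set(report.loc[report["included"], "participant_id"])
    return included, report


def astigmatism_covariate(left_deg: float, right_deg: float) -> float:
    """Participant astigmatism degree: mean of the two eyes."""
    if left_deg < 0 or right_deg < 0:
        raise InvalidInputError("astigmatism degrees must be nonnegative")
    return (left_deg + right_deg) / 2.0
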