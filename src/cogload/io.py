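"""Readers/writers for the three stream dialects, run configuration,
and the end-to-end pipeline.

Dialects (all plain text, timestamps in Unix seconds as floats):

* **EEG CSV** — header ``TimeStamp,RAW_TP9,RAW_AF7,RAW_AF8,RAW_TP10``;
  one row per sample at a fixed rate, amplitudes in µV.
* **Gaze TSV** — tab-separated with columns ``Recording timestamp``,
  ``Gaze point X``, ``Gaze point Y``, ``Pupil diameter left``,
  ``Pupil diameter right``, ``Validity left``, ``Validity right`` and
  optional ``Eye movement type`` / ``Gaze event duration`` columns
  carrying precomputed fixation/saccade events.  Validity is
  ``Valid``/``Invalid``; pupil cells are empty for invalid samples.
* **Task-log CSV** — ``id,n_back_order,letter,choice,accuracy,
  reaction_time,start_unix,end_unix,n_level``; ``accuracy`` is
  ``yes``/``no``/``null`` (null = unscoreable lead-in stimuli),
  ``choice`` is ``match``/``nonmatch``/``none``.  The stored reaction
  time is cross-checked against ``end_unix - start_unix`` on read.

Writers and readers round-trip losslessly on synthetic data; malformed
rows are counted, logged and skipped.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import NamedTuple, Optional, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .eeg import (
    CHANNELS,
    DEFAULT_BANDS,
    BandDef,
    EEGRecording,
    condition_means,
    erd_table,
)
from .errors import ConfigurationError, FormatError, IntegrityError
from .eye import (
    METRIC_FIELDS,
    CaptureRate,
    EyeEvent,
    capture_rate,
    filter_participants,
    interval_metrics,
    pupil_baseline,
)
from .simulate import (
    BehaviorSimConfig,
    EEGSimConfig,
    GazeSimConfig,
    SessionBundle,
    simulate_cohort,
)
from .stats import comparison_table, spearman
from .task import CONDITION_N_LEVEL, TaskConfig, TrialRecord, derive_response_key
from . import task as task_mod

logger = logging.getLogger("cogload.io")

__all__ = [
    "EEG_COLUMNS",
    "GAZE_TSV_COLUMNS",
    "TASK_LOG_COLUMNS",
    "write_eeg_csv",
    "read_eeg_csv",
    "write_gaze_tsv",
    "read_gaze_tsv",
    "write_task_log",
    "read_task_log",
    "RunConfig",
    "ResultsBundle",
    "run_all",
]

EEG_COLUMNS = ["TimeStamp"] + [f"RAW_{c}" for c in CHANNELS]

GAZE_TSV_COLUMNS = [
    "Recording timestamp",
    "Gaze point X",
    "Gaze point Y",
    "Pupil diameter left",
    "Pupil diameter right",
    "Validity left",
    "Validity right",
]
GAZE_EVENT_COLUMNS = ["Eye movement type", "Gaze event duration"]

TASK_LOG_COLUMNS = [
    "id", "n_back_order", "letter", "choice", "accuracy",
    "reaction_time", "start_unix", "end_unix", "n_level",
]


class EEGRead(NamedTuple):
    recording: EEGRecording
    n_skipped: int


class GazeRead(NamedTuple):
    stream: pd.DataFrame
    events: Optional[list[EyeEvent]]
    n_skipped: int


class TaskLogRead(NamedTuple):
    trials: dict[int, list[TrialRecord]]
    n_rows: int


# ---------------------------------------------------------------------------
# EEG CSV


def write_eeg_csv(recording: EEGRecording, path: str | Path) -> None:
    df = pd.DataFrame({"TimeStamp": recording.times()})
    for ch in recording.channels:
        df[f"RAW_{ch}"] = recording.channel(ch)
    df.to_csv(path, index=False, float_format="%.6f")


def read_eeg_csv(path: str | Path) -> EEGRead:
    """Parse the four-channel EEG CSV dialect.

    Malformed (non-numeric/incomplete) rows are skipped and counted.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype=str)
    missing = [c for c in EEG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required columns {missing}")
    numeric = df[EEG_COLUMNS].apply(pd.to_numeric, errors="coerce")
    good = numeric.notna().all(axis=1)
    n_skipped = int((~good).sum())
    if n_skipped:
        logger.warning("%s: skipped %d malformed rows", path.name, n_skipped)
    numeric = numeric[good]
    if len(numeric) < 2:
        raise FormatError(f"{path.name}: fewer than 2 valid samples")
    ts = numeric["TimeStamp"].to_numpy(dtype=float)
    if np.any(np.diff(ts) <= 0):
        raise FormatError(f"{path.name}: timestamps not strictly increasing")
    rate = 1.0 / float(np.median(np.diff(ts)))
    data = np.vstack([numeric[f"RAW_{c}"].to_numpy(dtype=float) for c in CHANNELS])
    return EEGRead(EEGRecording(data, CHANNELS, rate, float(ts[0])), n_skipped)


# ---------------------------------------------------------------------------
# Gaze TSV


def write_gaze_tsv(
    stream: pd.DataFrame,
    path: str | Path,
    events: Optional[Sequence[EyeEvent]] = None,
) -> None:
    out = pd.DataFrame(
        {
            "Recording timestamp": stream["ts"].map(lambda v: f"{v:.6f}"),
            "Gaze point X": stream["gaze_x"],
            "Gaze point Y": stream["gaze_y"],
            "Pupil diameter left": stream["pupil_left"],
            "Pupil diameter right": stream["pupil_right"],
            "Validity left": np.where(stream["valid_left"], "Valid", "Invalid"),
            "Validity right": np.where(stream["valid_right"], "Valid", "Invalid"),
        }
    )
    if events is not None:
        ts = stream["ts"].to_numpy(dtype=float)
        kind = np.full(len(ts), "", dtype=object)
        dur = np.full(len(ts), np.nan)
        for ev in events:
            mask = (ts >= ev.start_ts) & (ts < ev.end_ts)
            kind[mask] = ev.kind.capitalize()
            dur[mask] = ev.duration_ms
        out["Eye movement type"] = kind
        out["Gaze event duration"] = dur
    out.to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_gaze_tsv(path: str | Path) -> GazeRead:
    """Parse the gaze TSV dialect; precomputed events are returned when
    the event columns are present."""
    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in GAZE_TSV_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required columns {missing}")
    ts = pd.to_numeric(df["Recording timestamp"], errors="coerce")
    good = ts.notna()
    n_skipped = int((~good).sum())
    if n_skipped:
        logger.warning("%s: skipped %d malformed rows", path.name, n_skipped)
    df = df[good]
    ts = ts[good]
    valid_values = {"Valid", "Invalid"}
    for col in ("Validity left", "Validity right"):
        bad = set(df[col].dropna().unique()) - valid_values
        if bad:
            raise FormatError(f"{path.name}: unknown validity values {sorted(bad)}")
    stream = pd.DataFrame(
        {
            "ts": ts.to_numpy(dtype=float),
            "gaze_x": pd.to_numeric(df["Gaze point X"], errors="coerce"),
            "gaze_y": pd.to_numeric(df["Gaze point Y"], errors="coerce"),
            "pupil_left": pd.to_numeric(df["Pupil diameter left"], errors="coerce"),
            "pupil_right": pd.to_numeric(df["Pupil diameter right"], errors="coerce"),
            "valid_left": (df["Validity left"] == "Valid").to_numpy(),
            "valid_right": (df["Validity right"] == "Valid").to_numpy(),
        }
    ).reset_index(drop=True)
    events: Optional[list[EyeEvent]] = None
    if all(c in df.columns for c in GAZE_EVENT_COLUMNS):
        events = []
        kinds = df["Eye movement type"].fillna("").to_numpy()
        tsv = stream["ts"].to_numpy()
        i = 0
        while i < len(kinds):
            k = kinds[i]
            if k in ("Fixation", "Saccade"):
                j = i
                while j + 1 < len(kinds) and kinds[j + 1] == k:
                    j += 1
                dt = float(np.median(np.diff(tsv))) if len(tsv) > 1 else 0.0
                events.append(EyeEvent(k.lower(), float(tsv[i]), float(tsv[j]) + dt))
                i = j + 1
            else:
                i += 1
    return GazeRead(stream, events, n_skipped)


# ---------------------------------------------------------------------------
# Task log CSV


def write_task_log(
    trials: Sequence[TrialRecord],
    path: str | Path,
    orders: Optional[dict[int, str]] = None,
) -> None:
    rows = []
    for t in trials:
        order = (orders or {}).get(
            t.participant_id, "Order1" if t.participant_id % 2 else "Order2"
        )
        rows.append(
            {
                "id": t.participant_id,
                "n_back_order": order,
                "letter": t.letter,
                "choice": t.choice,
                "accuracy": (
                    "null" if t.correct is None else ("yes" if t.correct else "no")
                ),
                "reaction_time": "" if t.rt is None else f"{t.rt:.6f}",
                "start_unix": f"{t.onset_ts:.6f}",
                "end_unix": f"{(t.response_ts if t.response_ts is not None else t.onset_ts):.6f}",
                "n_level": t.n_level,
            }
        )
    pd.DataFrame(rows, columns=TASK_LOG_COLUMNS).to_csv(path, index=False)


def read_task_log(path: str | Path, rt_tolerance_s: float = 0.001) -> TaskLogRead:
    """Parse the behavioral log; recompute RT and cross-check the stored
    column within ``rt_tolerance_s`` (integrity error on mismatch)."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False)
    missing = [c for c in TASK_LOG_COLUMNS if c not in df.columns]
    if missing:
        raise FormatError(f"{path.name}: missing required columns {missing}")
    problems: list[str] = []
    trials: dict[int, list[TrialRecord]] = {}
    counters: dict[tuple[int, str], int] = {}
    for i, row in df.iterrows():
        pid = int(row["id"])
        n_level = int(row["n_level"])
        cond = "low" if n_level == 1 else "high"
        onset = float(row["start_unix"])
        end = float(row["end_unix"])
        rt_str = row["reaction_time"].strip()
        if rt_str == "":
            response = None
            if end < onset:
                problems.append(f"row {i}: end_unix before start_unix")
        else:
            rt = float(rt_str)
            if not np.isfinite(rt):
                problems.append(f"row {i}: non-finite reaction_time")
                continue
            response = end
            if end < onset:
                problems.append(f"row {i}: end_unix before start_unix")
            elif abs((end - onset) - rt) > rt_tolerance_s:
                problems.append(
                    f"row {i}: stored rt {rt:.4f}s disagrees with "
                    f"end-start {end - onset:.4f}s"
                )
        accuracy = row["accuracy"]
        correct = None if accuracy == "null" else accuracy == "yes"
        key = (pid, cond)
        idx = counters.get(key, 0)
        counters[key] = idx + 1
        trials.setdefault(pid, []).append(
            TrialRecord(
                participant_id=pid,
                block_label=cond,
                n_level=n_level,
                trial_index=idx,
                letter=row["letter"],
                onset_ts=onset,
                response_ts=response,
                choice=row["choice"],
                correct=correct,
            )
        )
    if problems:
        raise IntegrityError(
            f"{path.name}: {len(problems)} integrity problems: "
            + "; ".join(problems[:5])
        )
    return TaskLogRead(trials, len(df))


# ---------------------------------------------------------------------------
# Run configuration


@dataclass(frozen=True)
class RunConfig:
    """End-to-end pipeline configuration with strict key checking."""

    n_participants: int = 30
    dropout: tuple[int, ...] = (126,)
    seed: int = 0
    min_capture_rate: float = 0.6
    capture_spearman: float = -0.55
    baseline_modes: tuple[str, ...] = ("near", "away")
    bands: tuple[BandDef, ...] = DEFAULT_BANDS
    task: TaskConfig = field(default_factory=TaskConfig)
    eeg: EEGSimConfig = field(default_factory=EEGSimConfig)
    gaze: GazeSimConfig = field(default_factory=GazeSimConfig)
    behavior: BehaviorSimConfig = field(default_factory=BehaviorSimConfig)

    def to_dict(self) -> dict:
        def _plain(obj):
            if isinstance(obj, (BandDef, TaskConfig, EEGSimConfig, GazeSimConfig,
                                BehaviorSimConfig)):
                return {k: _plain(v) for k, v in vars(obj).items()}
            if isinstance(obj, dict):
                return {str(k): _plain(v) for k, v in obj.items()}
            if isinstance(obj, (list, tuple)):
                return [_plain(v) for v in obj]
            return obj

        return {k: _plain(v) for k, v in vars(self).items()}

    @property
    def config_hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:12]

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(raw) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        kwargs = {}
        nested = {
            "task": TaskConfig, "eeg": EEGSimConfig,
            "gaze": GazeSimConfig, "behavior": BehaviorSimConfig,
        }
        for key, value in raw.items():
            if key in nested and isinstance(value, dict):
                sub_cls = nested[key]
                sub_known = set(sub_cls.__dataclass_fields__)
                sub_unknown = set(value) - sub_known
                if sub_unknown:
                    raise ConfigurationError(
                        f"unknown {key} config keys: {sorted(sub_unknown)}"
                    )
                coerced = {
                    k: tuple(v) if isinstance(v, list) else v
                    for k, v in value.items()
                }
                kwargs[key] = sub_cls(**coerced)
            elif key == "bands" and isinstance(value, (list, tuple)):
                kwargs[key] = tuple(
                    b if isinstance(b, BandDef) else BandDef(**b) for b in value
                )
            elif isinstance(value, list):
                kwargs[key] = tuple(value)
            else:
                kwargs[key] = value
        return cls(**kwargs)


# ---------------------------------------------------------------------------
# End-to-end pipeline


@dataclass
class ResultsBundle:
    """All pipeline outputs plus provenance."""

    tables: dict[str, pd.DataFrame]
    screening: pd.DataFrame
    recovery: pd.DataFrame
    capture_correlation: dict
    exclusions: dict
    config_hash: str
    version: str = __version__


AWAY_MEASURES = (("Alpha", "AF7"), ("Alpha", "AF8"), ("Beta", "AF8"), ("Beta", "TP9"))


def _behavior_tables(bundles: list[SessionBundle]) -> dict[str, pd.DataFrame]:
    rt_rows, ar_rows = [], []
    for b in bundles:
        if b.dropped or b.trials is None:
            continue
        for cond in ("low", "high"):
            block = [t for t in b.trials if t.block_label == cond]
            key = derive_response_key(
                task_mod.LOW_WORKLOAD_LETTERS if cond == "low"
                else task_mod.HIGH_WORKLOAD_LETTERS,
                CONDITION_N_LEVEL[cond],
            )
            summary = task_mod.score_block(block, key, b.task_config)
            parity = "odd" if b.participant_id % 2 else "even"
            for rt in summary.rt_values:
                rt_rows.append(
                    {"condition": cond, "parity": parity, "value": rt}
                )
            ar_rows.append(
                {
                    "condition": cond,
                    "parity": parity,
                    "value": summary.accuracy_rate,
                }
            )
    rt = pd.DataFrame(rt_rows)
    ar = pd.DataFrame(ar_rows)
    parts = []
    rt_all = rt.assign(measure="Reaction time")
    parts.append(rt_all)
    for parity in ("odd", "even"):
        parts.append(
            rt[rt["parity"] == parity].assign(
                measure=f"Reaction time with {parity} IDs"
            )
        )
    parts.append(ar.assign(measure="Accuracy rate"))
    long = pd.concat(parts, ignore_index=True)
    table = comparison_table(
        long,
        measures=[
            "Reaction time",
            "Reaction time with odd IDs",
            "Reaction time with even IDs",
            "Accuracy rate",
        ],
    )
    return {"behavior": table, "_behavior_long": long}


def _eeg_tables(
    bundles: list[SessionBundle],
    bands: Sequence[BandDef],
    baseline_modes: Sequence[str],
) -> tuple[dict[str, pd.DataFrame], dict]:
    tables: dict[str, pd.DataFrame] = {}
    exclusions: dict[str, int] = {"no_samples": 0, "nonpositive_reference": 0}
    per_mode_rows: dict[str, list[pd.DataFrame]] = {m: [] for m in baseline_modes}
    for b in bundles:
        if b.dropped or b.recording is None or b.trials is None:
            continue
        for mode in baseline_modes:
            table, excl = erd_table(
                b.recording,
                b.trials,
                b.rest_interval[0],
                bands=bands,
                baseline_mode=mode,
                timeout_s=b.task_config.stimulus_timeout_s,
            )
            for k, v in excl.items():
                exclusions[k] += v
            table = table.assign(participant_id=b.participant_id)
            per_mode_rows[mode].append(table)
    for mode in baseline_modes:
        if not per_mode_rows[mode]:
            continue
        pooled = pd.concat(per_mode_rows[mode], ignore_index=True)
        if mode == "away":
            keep = {f"{b}_{'ERS' if b == 'Theta' else 'ERD'}_{c}_away"
                    for b, c in AWAY_MEASURES}
            pooled = pooled[pooled["measure"].isin(keep)]
        long = pooled.rename(
            columns={"block_label": "condition", "value_fraction": "value"}
        )
        tables[f"erd_{mode}"] = comparison_table(
            long, measures=sorted(long["measure"].unique())
        )
        tables[f"_erd_{mode}_long"] = long
    return tables, exclusions


def _eye_tables(
    bundles: list[SessionBundle],
    min_capture_rate: float,
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame, dict]:
    rates = []
    for b in bundles:
        if b.dropped or b.gaze is None:
            continue
        rates.append(capture_rate(b.gaze, b.participant_id))
    included, screening = filter_participants(rates, min_capture_rate)
    rows = []
    for b in bundles:
        if b.dropped or b.gaze is None or b.participant_id not in included:
            continue
        base = pupil_baseline(b.gaze, b.rest_interval)
        timeout = b.task_config.stimulus_timeout_s
        for t in b.trials or []:
            if t.correct is None:
                continue
            end = t.response_ts if t.response_ts is not None else (
                t.onset_ts + timeout
            )
            m = interval_metrics(
                b.gaze, b.events or [], (t.onset_ts, end), base
            )
            for name in METRIC_FIELDS:
                value = getattr(m, name)
                if value is None:
                    continue
                rows.append(
                    {
                        "participant_id": b.participant_id,
                        "condition": t.block_label,
                        "measure": name,
                        "value": value,
                    }
                )
    long = pd.DataFrame(rows)
    tables: dict[str, pd.DataFrame] = {}
    if len(long):
        tables["eye"] = comparison_table(long, measures=list(METRIC_FIELDS))
        tables["_eye_long"] = long
    # astigmatism vs capture rate across all recorded participants
    astig = []
    caps = []
    for b in bundles:
        if b.dropped or b.truth.capture_rate is None:
            continue
        astig.append(b.truth.astigmatism_deg)
        caps.append(b.truth.capture_rate)
    corr = None
    if len(astig) >= 3:
        result = spearman(astig, caps)
        corr = {"rho": result.rho, "p": result.p, "n": result.n}
    return tables, screening, corr or {}


def _recovery_report(
    bundles: list[SessionBundle],
    tables: dict[str, pd.DataFrame],
    capture_corr: dict,
    capture_spearman_target: float,
) -> pd.DataFrame:
    rows = []
    live = [b for b in bundles if not b.dropped]
    truth = live[0].truth
    if "_erd_near_long" in tables:
        means = condition_means(
            tables["_erd_near_long"].rename(
                columns={"condition": "block_label", "value": "value_fraction"}
            )
        )
        for _, r in means.iterrows():
            band, _, ch, _ = r["measure"].split("_")
            injected = truth.erd_truth.get((band, ch, r["block_label"]), 0.0)
            rows.append(
                {
                    "quantity": f"erd[{band},{ch},{r['block_label']}]",
                    "truth": injected,
                    "estimate": r["mean"],
                    "n": r["n"],
                }
            )
    if "_eye_long" in tables:
        eye = tables["_eye_long"]
        medians = {}
        for cond in ("low", "high"):
            sub = eye[
                (eye["measure"] == "avg_pupil_dilation_left")
                & (eye["condition"] == cond)
            ]["value"]
            if len(sub):
                medians[cond] = float(sub.median())
                rows.append(
                    {
                        "quantity": f"pupil_shift[{cond}]",
                        "truth": truth.pupil_shift_mm[cond],
                        "estimate": medians[cond],
                        "n": len(sub),
                    }
                )
        if len(medians) == 2:
            # the condition difference cancels per-participant baseline noise
            rows.append(
                {
                    "quantity": "pupil_shift[high-low]",
                    "truth": truth.pupil_shift_mm["high"]
                    - truth.pupil_shift_mm["low"],
                    "estimate": medians["high"] - medians["low"],
                    "n": 0,
                }
            )
    if "_behavior_long" in tables:
        beh = tables["_behavior_long"]
        for cond in ("low", "high"):
            sub = beh[
                (beh["measure"] == "Reaction time") & (beh["condition"] == cond)
            ]["value"]
            mu, _ = truth.rt_lognormal[cond]
            rows.append(
                {
                    "quantity": f"rt_median[{cond}]",
                    "truth": float(np.exp(mu)),
                    "estimate": float(sub.median()),
                    "n": len(sub),
                }
            )
            sub = beh[
                (beh["measure"] == "Accuracy rate") & (beh["condition"] == cond)
            ]["value"]
            # timeouts score incorrect, so the expected AR is the
            # Bernoulli p times the probability of answering in time
            mu_c, sd_c = truth.rt_lognormal[cond]
            from scipy.stats import norm

            timeout_s = live[0].task_config.stimulus_timeout_s
            p_answer = float(norm.cdf((np.log(timeout_s) - mu_c) / sd_c))
            rows.append(
                {
                    "quantity": f"accuracy[{cond}]",
                    "truth": truth.accuracy_p[cond] * p_answer,
                    "estimate": float(sub.mean()),
                    "n": len(sub),
                }
            )
    if capture_corr:
        rows.append(
            {
                "quantity": "capture_astigmatism_spearman",
                "truth": capture_spearman_target,
                "estimate": capture_corr["rho"],
                "n": capture_corr["n"],
            }
        )
    report = pd.DataFrame(rows)
    if len(report):
        report["abs_error"] = (report["estimate"] - report["truth"]).abs()
    return report


def run_all(
    config: Optional[RunConfig] = None,
    *,
    seed: Optional[int] = None,
    out_dir: Optional[str | Path] = None,
) -> ResultsBundle:
    """Simulate a cohort and run every analysis stage on it.

    Deterministic under a fixed config/seed.  When ``out_dir`` is
    given, every public table is written as CSV with a provenance
    comment line, alongside ``run_metadata.json``.
    """
    config = config or RunConfig()
    if seed is not None:
        config = RunConfig.from_dict({**config.to_dict(), "seed": seed})
    bundles = simulate_cohort(
        config.n_participants,
        seed=config.seed,
        dropout=set(config.dropout),
        task_config=config.task,
        eeg_config=config.eeg,
        gaze_config=config.gaze,
        behavior_config=config.behavior,
        capture_spearman=config.capture_spearman,
    )
    tables = _behavior_tables(bundles)
    eeg_tables, exclusions = _eeg_tables(bundles, config.bands, config.baseline_modes)
    tables.update(eeg_tables)
    eye_tables, screening, corr = _eye_tables(bundles, config.min_capture_rate)
    tables.update(eye_tables)
    recovery = _recovery_report(bundles, tables, corr, config.capture_spearman)
    results = ResultsBundle(
        tables={k: v for k, v in tables.items() if not k.startswith("_")},
        screening=screening,
        recovery=recovery,
        capture_correlation=corr,
        exclusions=exclusions,
        config_hash=config.config_hash,
    )
    if out_dir is not None:
        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        stamp = f"# cogload {__version__} config_hash={results.config_hash}\n"
        for name, table in {
            **results.tables,
            "screening": results.screening,
            "recovery": results.recovery,
        }.items():
            target = out / f"{name}.csv"
            with open(target, "w") as fh:
                fh.write(stamp)
                table.to_csv(fh, index=False)
        (out / "run_metadata.json").write_text(
            json.dumps(
                {
                    "version": __version__,
                    "config_hash": results.config_hash,
                    "config": config.to_dict(),
                    "capture_correlation": results.capture_correlation,
                    "exclusions": results.exclusions,
                },
                indent=2,
                default=str,
            )
        )
    return results
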