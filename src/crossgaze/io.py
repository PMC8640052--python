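"""Delimited-text round-tripping for every pipeline artifact.

All formats are plain TSV/CSV with documented columns; schema violations
raise errors naming the offending column.  Gaze traces serialize one file
per participant-session with columns (trial_id, interval, t_ms, gaze_x_deg,
gaze_y_deg, pupil_valid).
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .observer import GazeTrace
from .preprocess import EventLabels
from .scene import DesignGrid, SceneConfig

__all__ = [
    "write_trials", "read_trials",
    "write_traces", "read_traces",
    "write_events", "read_events",
    "write_metrics", "read_metrics",
    "load_config", "save_config",
]

TRIAL_COLUMNS = {
    "participant_id": str, "task": str, "block": int, "trial_index": int,
    "comparison_speed": float, "comparison_tta": float,
    "standard_first": bool, "approach_side": str,
}
TRACE_COLUMNS = ["trial_id", "interval", "t_ms", "gaze_x_deg", "gaze_y_deg",
                 "pupil_valid"]
EVENT_COLUMNS = ["trial_id", "interval", "kind", "onset_ms", "offset_ms",
                 "amplitude_deg"]


class SchemaError(ValueError):
    pass


def _require(df: pd.DataFrame, columns, where: str) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise SchemaError(f"{where}: missing columns {missing}")


def write_trials(trials: pd.DataFrame, path) -> None:
    _require(trials, TRIAL_COLUMNS, "trial table")
    trials.to_csv(path, sep="\t", index=False)


def read_trials(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    _require(df, TRIAL_COLUMNS, str(path))
    for col, typ in TRIAL_COLUMNS.items():
        try:
            df[col] = df[col].astype(typ)
        except (ValueError, TypeError) as exc:
            raise SchemaError(f"{path}: column {col!r} not parseable as "
                              f"{typ.__name__}: {exc}") from exc
    return df


def write_traces(traces: dict, path) -> None:
    """One TSV per participant-session under ``path`` (a directory)."""
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    by_session: dict[tuple, list] = {}
    for (pid, task, trial, interval), tr in traces.items():
        by_session.setdefault((pid, task), []).append((trial, interval, tr))
    for (pid, task), items in by_session.items():
        frames = []
        for trial, interval, tr in items:
            frames.append(pd.DataFrame({
                "trial_id": trial, "interval": interval,
                "t_ms": tr.t_ms, "gaze_x_deg": tr.gaze_x,
                "gaze_y_deg": tr.gaze_y,
                "pupil_valid": tr.pupil_valid.astype(int)}))
        pd.concat(frames).to_csv(path / f"gaze_{pid}_{task}.tsv", sep="\t",
                                 index=False, float_format="%.6g")


def read_traces(path) -> dict:
    path = Path(path)
    traces: dict[tuple, GazeTrace] = {}
    for f in sorted(path.glob("gaze_*.tsv")):
        _, pid, task = f.stem.split("_", 2)
        df = pd.read_csv(f, sep="\t")
        _require(df, TRACE_COLUMNS, str(f))
        if not np.issubdtype(df["t_ms"].dtype, np.number):
            raise SchemaError(f"{f}: column 't_ms' must be numeric")
        for (trial, interval), grp in df.groupby(["trial_id", "interval"]):
            t = grp["t_ms"].to_numpy(dtype=float)
            rate = 1000.0 / float(t[1] - t[0]) if len(t) > 1 else 1000.0
            traces[(pid, task, int(trial), interval)] = GazeTrace(
                trial_id=int(trial), interval=interval, t_ms=t,
                gaze_x=grp["gaze_x_deg"].to_numpy(dtype=float),
                gaze_y=grp["gaze_y_deg"].to_numpy(dtype=float),
                pupil_valid=grp["pupil_valid"].to_numpy(dtype=bool),
                sample_rate=rate)
    return traces


def write_events(events: dict, path) -> None:
    """``events``: (pid, task, trial, interval) -> EventLabels."""
    rows = []
    for (pid, task, trial, interval), ev in events.items():
        for on, off, amp, _d in ev.saccades:
            rows.append((pid, task, trial, interval, "saccade", on, off, amp))
        for on, off in ev.blinks:
            rows.append((pid, task, trial, interval, "blink", on, off, np.nan))
    pd.DataFrame(rows, columns=["participant_id", "task"] + EVENT_COLUMNS) \
        .to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_events(path) -> dict:
    df = pd.read_csv(path, sep="\t")
    _require(df, ["participant_id", "task"] + EVENT_COLUMNS, str(path))
    out: dict[tuple, EventLabels] = {}
    for r in df.itertuples():
        key = (r.participant_id, r.task, int(r.trial_id), r.interval)
        ev = out.setdefault(key, EventLabels())
        if r.kind == "saccade":
            ev.saccades.append((r.onset_ms, r.offset_ms, r.amplitude_deg, np.nan))
        else:
            ev.blinks.append((r.onset_ms, r.offset_ms))
    return out


def write_metrics(metrics: pd.DataFrame, path) -> None:
    metrics.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_metrics(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def save_config(scene: SceneConfig, grid: DesignGrid, path,
                extra: dict | None = None) -> None:
    doc = {"scene": {k: list(v) if isinstance(v, tuple) else v
                     for k, v in scene.__dict__.items()},
           "design": {k: list(v) if isinstance(v, tuple) else v
                      for k, v in grid.__dict__.items()}}
    if extra:
        doc.update(extra)
    with open(path, "w") as fh:
        yaml.safe_dump(doc, fh, sort_keys=False)


def load_config(path) -> dict:
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    out = dict(doc)
    if "scene" in doc:
        kw = {k: tuple(v) if isinstance(v, list) else v
              for k, v in doc["scene"].items()}
        out["scene"] = SceneConfig(**kw)
    if "design" in doc:
        kw = {k: tuple(v) if isinstance(v, list) else v
              for k, v in doc["design"].items()}
        out["design"] = DesignGrid(**kw)
    return out
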