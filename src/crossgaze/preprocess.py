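"""Saccade/blink detection, trace cleaning and exclusion rules.

The detector approximates the EyeLink online parser from its published
parameters: a sample is saccadic when 2D gaze speed exceeds 22 deg/s plus an
adaptive pursuit allowance (trailing 40 ms mean speed over non-saccadic
samples, capped so that the effective threshold never exceeds the 60 deg/s
fixup limit), or when acceleration exceeds 5000 deg/s^2.  Velocity comes
from central differences on unsmoothed samples, acceleration from the
differenced velocity vector.  Events shorter than 6 ms are discarded and
events separated by under 20 ms merged (unstated in the original; suppresses
single-sample flicker).  Blinks are maximal invalid-pupil runs padded by
20 ms per side.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .scene import SceneConfig, screen_to_eye_unit

__all__ = [
    "DetectorConfig",
    "EventLabels",
    "CleaningReport",
    "detect_saccades",
    "detect_blinks",
    "clean_trace",
    "apply_exclusions",
]


@dataclass(frozen=True)
class DetectorConfig:
    velocity_threshold: float = 22.0  # deg/s
    acceleration_threshold: float = 5000.0  # deg/s^2
    pursuit_window: float = 40.0  # ms
    fixup_limit: float = 60.0  # deg/s
    min_duration: float = 6.0  # ms
    merge_gap: float = 20.0  # ms
    # short boxcar on the velocity estimate (the hardware parser applies a
    # comparable velocity model); keeps white tracker noise from tripping
    # the acceleration criterion at high sampling rates
    velocity_smooth: float = 5.0  # ms
    edge_guard: float = 20.0  # ms: velocity undefined at the trace boundary

    def __post_init__(self) -> None:
        if min(self.velocity_threshold, self.acceleration_threshold,
               self.pursuit_window, self.fixup_limit) <= 0:
            raise ValueError("detector parameters must be positive")
        if self.fixup_limit < self.velocity_threshold:
            raise ValueError("fixup_limit must be >= velocity_threshold")


@dataclass
class EventLabels:
    """Saccade and blink annotations for one trace (times in ms)."""

    saccades: list = field(default_factory=list)  # (onset, offset, amp, dir)
    blinks: list = field(default_factory=list)  # (onset, offset)

    def saccade_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.saccades,
                            columns=["onset_ms", "offset_ms",
                                     "amplitude_deg", "direction_deg"])


@dataclass
class CleaningReport:
    interpolated_fraction: dict  # key -> fraction
    excluded_trials: list  # (key, reason)
    excluded_participants: list  # (participant, task)


def _check_uniform(t_ms: np.ndarray) -> float:
    dt = np.diff(t_ms)
    if len(dt) == 0 or not np.allclose(dt, dt[0], rtol=0, atol=1e-6):
        raise ValueError("gaze trace must have uniform timestamps")
    return float(dt[0])


def _speed_accel(trace, cfg: DetectorConfig):
    """Per-sample 2D gaze speed (deg/s) and acceleration magnitude."""
    dt = _check_uniform(trace.t_ms) / 1000.0
    x, y = trace.gaze_x, trace.gaze_y
    vx = np.gradient(x, dt)
    vy = np.gradient(y, dt)
    n_sm = max(1, int(round(cfg.velocity_smooth / 1000.0 / dt)))
    if n_sm > 1:
        kernel = np.ones(n_sm) / n_sm
        vx = np.convolve(vx, kernel, mode="same")
        vy = np.convolve(vy, kernel, mode="same")
    speed = np.hypot(vx, vy)
    # acceleration differenced over +-2 samples: a single-sample base on
    # smoothed velocity amplifies residual noise far above the threshold
    k = min(2, (len(vx) - 1) // 2)
    ax = np.empty_like(vx)
    ay = np.empty_like(vy)
    ax[k:-k] = (vx[2 * k:] - vx[:-2 * k]) / (2 * k * dt)
    ay[k:-k] = (vy[2 * k:] - vy[:-2 * k]) / (2 * k * dt)
    ax[:k], ax[-k:] = ax[k], ax[-k - 1]
    ay[:k], ay[-k:] = ay[k], ay[-k - 1]
    accel = np.hypot(ax, ay)
    return speed, accel, dt


def _trailing_mean(values: np.ndarray, n: int, mask: np.ndarray) -> np.ndarray:
    """Trailing mean over the previous n samples, ignoring masked samples."""
    v = np.where(mask, np.nan, values)
    s = pd.Series(v).shift(1).rolling(n, min_periods=1).mean().to_numpy()
    return np.nan_to_num(s, nan=0.0)


def _runs(flags: np.ndarray) -> list[tuple[int, int]]:
    """[start, end) index pairs of True runs."""
    if not flags.any():
        return []
    d = np.diff(flags.astype(np.int8))
    starts = list(np.where(d == 1)[0] + 1)
    ends = list(np.where(d == -1)[0] + 1)
    if flags[0]:
        starts.insert(0, 0)
    if flags[-1]:
        ends.append(len(flags))
    return list(zip(starts, ends))


def detect_saccades(trace, cfg: DetectorConfig | None = None,
                    scene: SceneConfig | None = None) -> EventLabels:
    """Velocity/acceleration-threshold saccade detection with pursuit fixup.

    Two vectorized passes: the adaptive pursuit allowance is first computed
    over all samples, then recomputed with first-pass saccadic samples
    excluded (the allowance should reflect pursuit, not saccades).
    """
    cfg = cfg or DetectorConfig()
    speed, accel, dt = _speed_accel(trace, cfg)
    if len(trace.t_ms) * dt * 1000.0 < 50.0:
        raise ValueError("need at least 50 ms of data to detect saccades")
    n_win = max(1, int(round(cfg.pursuit_window / 1000.0 / dt)))
    allowance_cap = cfg.fixup_limit - cfg.velocity_threshold

    mask = np.zeros(len(speed), dtype=bool)
    for _ in range(2):
        pursuit = np.minimum(_trailing_mean(speed, n_win, mask), allowance_cap)
        mask = (speed > cfg.velocity_threshold + pursuit) | \
               (accel > cfg.acceleration_threshold)

    # drop sub-minimum flickers first, then merge nearby events (merging
    # before filtering would let isolated noise samples coalesce)
    min_len = max(1, int(round(cfg.min_duration / 1000.0 / dt)))
    gap = int(round(cfg.merge_gap / 1000.0 / dt))
    runs = [(s, e) for s, e in _runs(mask) if e - s >= min_len]
    merged: list[list[int]] = []
    for s, e in runs:
        if merged and s - merged[-1][1] <= gap:
            merged[-1][1] = e
        else:
            merged.append([s, e])
    guard = cfg.edge_guard / 1000.0 / dt
    events = []
    dirs = screen_to_eye_unit(trace.gaze_x, trace.gaze_y)
    for s, e in merged:
        if e - s < min_len or s < guard:
            continue
        e_idx = min(e, len(speed) - 1)
        u0, u1 = dirs[s], dirs[min(e_idx, len(dirs) - 1)]
        amp = float(np.degrees(np.arccos(np.clip(np.dot(u0, u1), -1.0, 1.0))))
        direction = float(np.degrees(np.arctan2(
            trace.gaze_y[e_idx] - trace.gaze_y[s],
            trace.gaze_x[e_idx] - trace.gaze_x[s])))
        events.append((float(trace.t_ms[s]), float(trace.t_ms[e_idx]),
                       amp, direction))
    return EventLabels(saccades=events, blinks=[])


def detect_blinks(trace, pad_ms: float = 20.0) -> EventLabels:
    """Blinks as padded maximal runs of invalid pupil samples."""
    valid = np.asarray(trace.pupil_valid, dtype=bool)
    if valid.all():
        return EventLabels()
    dt = _check_uniform(trace.t_ms)
    t0 = float(trace.t_ms[0])
    t_end = float(trace.t_ms[-1]) + dt
    blinks = []
    for s, e in _runs(~valid):
        on = max(t0, trace.t_ms[s] - pad_ms)
        off = min(t_end, trace.t_ms[min(e, len(valid) - 1)] + pad_ms)
        if blinks and on <= blinks[-1][1]:
            blinks[-1] = (blinks[-1][0], max(blinks[-1][1], off))
        else:
            blinks.append((float(on), float(off)))
    return EventLabels(blinks=blinks)


def clean_trace(trace, events: EventLabels):
    """Remove event windows and interpolate linearly.

    Returns ``(cleaned_trace, interpolated_fraction)``.  Samples inside any
    saccade or blink window are replaced by linear interpolation between the
    flanking valid samples; leading/trailing gaps take the nearest valid
    value.  Raises if no valid sample remains.
    """
    from copy import copy

    t = trace.t_ms
    bad = np.zeros(len(t), dtype=bool)
    for on, off, *_ in list(events.saccades) + [(b[0], b[1]) for b in events.blinks]:
        bad |= (t >= on) & (t <= off)
    frac = float(bad.mean())
    if bad.all():
        raise ValueError("unusable trial: no valid samples remain")
    out = copy(trace)
    good = ~bad
    out.gaze_x = np.interp(t, t[good], trace.gaze_x[good])
    out.gaze_y = np.interp(t, t[good], trace.gaze_y[good])
    out.pupil_valid = np.ones(len(t), dtype=bool)
    return out, frac


def preprocess_trace(trace, cfg: DetectorConfig | None = None,
                     scene: SceneConfig | None = None):
    """Detect blinks and saccades, clean, and return (trace', events, frac)."""
    blinks = detect_blinks(trace)
    saccades = detect_saccades(trace, cfg, scene)
    events = EventLabels(saccades=saccades.saccades, blinks=blinks.blinks)
    cleaned, frac = clean_trace(trace, events)
    return cleaned, events, frac


def apply_exclusions(fractions: pd.DataFrame, trial_threshold: float = 0.5,
                     participant_threshold: float = 0.5):
    """Apply the trial/participant exclusion rules.

    ``fractions`` has one row per trial with columns ``participant_id``,
    ``task``, ``trial_index``, ``frac_standard``, ``frac_comparison``.
    A trial is dropped when the interpolated fraction exceeds the threshold
    in *either* interval; a participant is dropped from a task when their
    dropped trials exceed half of that task's trials.
    """
    df = fractions.copy()
    df["excluded"] = (df["frac_standard"] > trial_threshold) | \
                     (df["frac_comparison"] > trial_threshold)
    excluded_trials = [((r.participant_id, r.task, r.trial_index),
                        "interpolated fraction > %.0f%%" % (100 * trial_threshold))
                       for r in df[df["excluded"]].itertuples()]
    excluded_participants = []
    for (pid, task), grp in df.groupby(["participant_id", "task"], sort=True):
        if grp["excluded"].mean() > participant_threshold:
            excluded_participants.append((pid, task))
    keep = df[~df["excluded"]].copy()
    keep = keep[~keep.set_index(["participant_id", "task"]).index.isin(
        excluded_participants)]
    report = CleaningReport(
        interpolated_fraction={
            (r.participant_id, r.task, r.trial_index):
                (r.frac_standard, r.frac_comparison)
            for r in df.itertuples()},
        excluded_trials=excluded_trials,
        excluded_participants=excluded_participants,
    )
    return keep.drop(columns=["excluded"]), report
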