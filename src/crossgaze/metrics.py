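"""Per-trial gaze features: pursuit gain, AOI deviations, saccade statistics.

Pursuit gain is the ratio of eye to target angular velocity.  Both series
are computed from the cross product of consecutive 3D direction vectors in
the world/eye reference frame (more accurate than planar screen speeds at
oblique gaze angles), low-pass filtered with a zero-phase second-order
Butterworth at 10 Hz, and averaged — by default over the 2-3 s window before
the vehicle disappears, where its retinal speed is high enough for a stable
gain estimate.  Deviations are measured from the dynamic vehicle-AOI center;
the horizontal sign is flipped for left-approach trials so that positive
always means "ahead, in the motion direction".
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal

from .preprocess import DetectorConfig, EventLabels, preprocess_trace
from .scene import (
    AoiBox,
    SceneConfig,
    Trajectory,
    aoi_center_path,
    crossing_aoi,
    screen_to_unit,
)

__all__ = [
    "MetricsConfig",
    "OutlierConfig",
    "TrialGazeMetrics",
    "angular_velocity_3d",
    "pursuit_gain",
    "position_deviation",
    "saccade_stats",
    "mad_outlier_filter",
    "compute_trial_metrics",
    "compute_metrics_table",
    "FEATURE_COLUMNS",
]

FEATURE_COLUMNS = ["gain", "rel_dev_v", "rel_dev_h", "abs_dev_v", "abs_dev_h",
                   "n_saccades", "mean_amplitude",
                   "n_sacc_crossing_before", "n_sacc_crossing_after"]


@dataclass(frozen=True)
class MetricsConfig:
    gain_window: tuple[float, float] = (2.0, 3.0)  # s, descriptive window
    glmm_window: tuple[float, float] = (0.0, 3.0)  # full visible interval
    butterworth_order: int = 2
    butterworth_cutoff: float = 10.0  # Hz


@dataclass(frozen=True)
class OutlierConfig:
    symmetric_cutoff: float = 3.5
    asymmetric_cutoff: float = 4.5
    asymmetric_metrics: tuple[str, ...] = ("n_saccades", "mean_amplitude")
    mad_scale_constant: float = 1.4826


@dataclass
class TrialGazeMetrics:
    gain: float
    rel_dev_h: float
    rel_dev_v: float
    abs_dev_h: float
    abs_dev_v: float
    n_saccades: int
    mean_amplitude: float
    n_sacc_crossing_before: int
    n_sacc_crossing_after: int


def angular_velocity_3d(gaze_dirs: np.ndarray, dt: float) -> np.ndarray:
    """Angular speed (deg/s) from consecutive unit direction vectors.

    omega_i = asin(||u_i x u_{i+1}||) / dt; returns length n-1.
    """
    u = np.asarray(gaze_dirs, dtype=float)
    norms = np.linalg.norm(u, axis=1)
    if np.any(norms == 0):
        raise ValueError("zero direction vector")
    u = u / norms[:, None]
    cross = np.cross(u[:-1], u[1:])
    s = np.clip(np.linalg.norm(cross, axis=1), 0.0, 1.0)
    return np.degrees(np.arcsin(s)) / dt


def _omega_vector(dirs: np.ndarray, dt: float) -> np.ndarray:
    """Angular-velocity vectors (deg/s) from consecutive unit directions."""
    u = np.asarray(dirs, dtype=float)
    u = u / np.linalg.norm(u, axis=1)[:, None]
    cross = np.cross(u[:-1], u[1:])
    s = np.linalg.norm(cross, axis=1)
    angle = np.degrees(np.arcsin(np.clip(s, 0.0, 1.0)))
    with np.errstate(invalid="ignore", divide="ignore"):
        axis = np.where(s[:, None] > 0, cross / np.where(s == 0, 1, s)[:, None], 0.0)
    return axis * (angle / dt)[:, None]


def _filtered_speed(dirs: np.ndarray, dt: float, cfg: MetricsConfig) -> np.ndarray:
    """Low-pass the angular-velocity vector components, then take magnitudes.

    Filtering the components (rather than the rectified speed) lets
    zero-mean tracker noise average out instead of biasing the mean speed.
    """
    nyq = 0.5 / dt
    if cfg.butterworth_cutoff >= nyq:
        raise ValueError("Butterworth cutoff must be below Nyquist")
    b, a = signal.butter(cfg.butterworth_order, cfg.butterworth_cutoff / nyq)
    w = signal.filtfilt(b, a, _omega_vector(dirs, dt), axis=0)
    return np.linalg.norm(w, axis=1)


def pursuit_gain(trace, traj: Trajectory, cfg: MetricsConfig | None = None,
                 scene: SceneConfig | None = None,
                 window: tuple[float, float] | None = None,
                 exclude_ms: list[tuple[float, float]] | None = None,
                 exclude_pad_ms: float = 100.0) -> float:
    """Mean filtered gaze angular speed over mean target angular speed.

    Expects a cleaned trace (saccades interpolated out).  ``exclude_ms``
    windows (detected saccades/blinks, padded for filter smear) are dropped
    from the average so the estimate reflects smooth pursuit rather than
    interpolated saccadic displacement.  Returns NaN when the target barely
    moves in the window (undefined gain).
    """
    cfg = cfg or MetricsConfig()
    scene = scene or SceneConfig()
    window = window or cfg.gain_window
    dt = float(trace.t_ms[1] - trace.t_ms[0]) / 1000.0
    gaze_dirs = screen_to_unit(trace.gaze_x, trace.gaze_y, scene)
    tgt_dirs = traj.world_points / np.linalg.norm(traj.world_points, axis=1)[:, None]
    w_gaze = _filtered_speed(gaze_dirs, dt, cfg)
    w_tgt = _filtered_speed(tgt_dirs, dt, cfg)
    t_mid_ms = (trace.t_ms[:-1] + trace.t_ms[1:]) / 2.0
    sel = (t_mid_ms >= window[0] * 1000.0) & (t_mid_ms < window[1] * 1000.0)
    for on, off in exclude_ms or []:
        sel &= ~((t_mid_ms >= on - exclude_pad_ms) & (t_mid_ms <= off + exclude_pad_ms))
    if not sel.any():
        return float("nan")
    denom = float(np.mean(w_tgt[sel]))
    if denom < 1e-9:
        return float("nan")
    return float(np.mean(w_gaze[sel]) / denom)


def position_deviation(trace, aoi_centers: np.ndarray,
                       window: tuple[float, float],
                       approach_side: str = "right") -> tuple[float, float, float, float]:
    """(rel_h, rel_v, abs_h, abs_v) deviation of gaze from the AOI center.

    Relative deviations keep the sign (positive = above / ahead in the
    motion direction); absolute deviations average magnitudes.
    """
    t_s = trace.t_ms / 1000.0
    sel = (t_s >= window[0]) & (t_s < window[1])
    if not sel.any():
        raise ValueError("empty deviation window")
    dx = trace.gaze_x[sel] - aoi_centers[sel, 0]
    dy = trace.gaze_y[sel] - aoi_centers[sel, 1]
    # vehicles drift outward from the screen center as they approach, so
    # "ahead" is +x for right-side approaches and -x for left-side ones
    sign = 1.0 if approach_side == "right" else -1.0
    rel_h = float(np.mean(sign * dx))
    rel_v = float(np.mean(dy))
    abs_h = float(np.mean(np.abs(dx)))
    abs_v = float(np.mean(np.abs(dy)))
    return rel_h, rel_v, abs_h, abs_v


def saccade_stats(events: EventLabels, crossing: AoiBox,
                  vehicle_offset_time: float, trace=None) -> dict:
    """Saccade count/amplitude after discarding the first post-onset saccade.

    Crossing-AOI saccades are those whose endpoint gaze position lands in
    the crossing box, split at the vehicle offset time.
    """
    sacc = sorted(events.saccades, key=lambda s: s[0])
    kept = sacc[1:]  # first saccade after vehicle onset removed
    n = len(kept)
    mean_amp = float(np.mean([s[2] for s in kept])) if kept else float("nan")
    before = after = 0
    if trace is not None:
        for on, off, amp, _dir in sacc:
            i = int(np.searchsorted(trace.t_ms, off))
            i = min(i, len(trace.t_ms) - 1)
            if crossing.contains(float(trace.gaze_x[i]), float(trace.gaze_y[i])):
                if off / 1000.0 <= vehicle_offset_time:
                    before += 1
                else:
                    after += 1
    return {"n_saccades": n, "mean_amplitude": mean_amp,
            "n_sacc_crossing_before": before, "n_sacc_crossing_after": after}


def _mad(x: np.ndarray) -> float:
    return float(np.median(np.abs(x - np.median(x))))


def mad_outlier_filter(values, cfg: OutlierConfig | None = None,
                       asymmetric: bool = False) -> np.ndarray:
    """Keep-mask from the (double-)MAD criterion.

    Symmetric: flag |x - median| / (c * MAD) > 3.5.  Asymmetric (double
    MAD, for skewed counts/amplitudes): separate MADs for values below and
    above the median, each side flagged above 4.5.  A zero MAD on a side
    flags nothing there (guarded) and emits a warning.
    """
    cfg = cfg or OutlierConfig()
    x = np.asarray(values, dtype=float)
    finite = np.isfinite(x)
    if finite.sum() < 3:
        raise ValueError("need at least 3 finite values")
    keep = np.ones(len(x), dtype=bool)
    med = float(np.median(x[finite]))
    c = cfg.mad_scale_constant
    if not asymmetric:
        mad = _mad(x[finite])
        if mad == 0:
            warnings.warn("MAD is zero; no outliers flagged")
            return keep
        score = np.abs(x - med) / (c * mad)
        keep[finite] = score[finite] <= cfg.symmetric_cutoff
    else:
        lo = x[finite & (x <= med)]
        hi = x[finite & (x >= med)]
        # deviations are taken from the overall median on each side
        mad_lo = float(np.median(np.abs(lo - med))) if len(lo) else 0.0
        mad_hi = float(np.median(np.abs(hi - med))) if len(hi) else 0.0
        for side_mask, mad_side in (((x < med), mad_lo), ((x > med), mad_hi)):
            if mad_side == 0:
                if side_mask[finite].any():
                    warnings.warn("one-sided MAD is zero; side left unfiltered")
                continue
            score = np.abs(x - med) / (c * mad_side)
            flag = side_mask & finite & (score > cfg.asymmetric_cutoff)
            keep[flag] = False
    return keep


def compute_trial_metrics(trace, traj: Trajectory, scene: SceneConfig,
                          cfg: MetricsConfig | None = None,
                          detector: DetectorConfig | None = None,
                          window: tuple[float, float] | None = None,
                          approach_side: str = "right") -> TrialGazeMetrics:
    """Full feature vector for one trial-interval from a raw trace."""
    cfg = cfg or MetricsConfig()
    window = window or cfg.gain_window
    cleaned, events, _frac = preprocess_trace(trace, detector, scene)
    centers = aoi_center_path(traj, scene)
    windows = [(s[0], s[1]) for s in events.saccades] + list(events.blinks)
    gain = pursuit_gain(cleaned, traj, cfg, scene, window=window,
                        exclude_ms=windows)
    rel_h, rel_v, abs_h, abs_v = position_deviation(
        cleaned, centers, window, approach_side)
    # saccade stats always use events within the visible interval
    vis_end_ms = scene.display_duration * 1000.0
    vis_events = EventLabels(
        saccades=[s for s in events.saccades if s[0] < vis_end_ms + 2000.0],
        blinks=events.blinks)
    stats = saccade_stats(vis_events, crossing_aoi(scene),
                          scene.display_duration, trace=trace)
    return TrialGazeMetrics(gain=gain, rel_dev_h=rel_h, rel_dev_v=rel_v,
                            abs_dev_h=abs_h, abs_dev_v=abs_v,
                            n_saccades=stats["n_saccades"],
                            mean_amplitude=stats["mean_amplitude"],
                            n_sacc_crossing_before=stats["n_sacc_crossing_before"],
                            n_sacc_crossing_after=stats["n_sacc_crossing_after"])


def compute_metrics_table(dataset: dict, window: str = "feature",
                          cfg: MetricsConfig | None = None,
                          detector: DetectorConfig | None = None,
                          intervals: tuple[str, ...] = ("comparison",)) -> pd.DataFrame:
    """Metrics for every trace of a generated dataset.

    ``window`` selects the averaging span for gain/deviations: ``"feature"``
    (2-3 s, descriptive/classification use) or ``"full"`` (whole visible
    interval, performance-model use).
    """
    from .scene import make_trajectory

    cfg = cfg or MetricsConfig()
    win = cfg.gain_window if window == "feature" else cfg.glmm_window
    scene, grid = dataset["scene"], dataset["grid"]
    trials = dataset["trials"]
    traces = dataset["traces"]
    rate = next(iter(traces.values())).sample_rate if traces else 1000.0
    traj_cache: dict[tuple, Trajectory] = {}

    def get_traj(speed, tta, side):
        key = (speed, tta, side)
        if key not in traj_cache:
            traj_cache[key] = make_trajectory(speed, tta, side, scene, rate)
        return traj_cache[key]

    rows = []
    for r in trials.itertuples():
        for interval in intervals:
            key = (r.participant_id, r.task, r.trial_index, interval)
            if key not in traces:
                continue
            if interval == "comparison":
                sp, tt = r.comparison_speed, r.comparison_tta
            else:
                sp, tt = grid.standard_speed, grid.standard_tta
            traj = get_traj(sp, tt, r.approach_side)
            m = compute_trial_metrics(traces[key], traj, scene, cfg, detector,
                                      window=win, approach_side=r.approach_side)
            rows.append({"participant_id": r.participant_id, "task": r.task,
                         "trial_index": r.trial_index, "interval": interval,
                         "window": window, "correct": r.correct,
                         "comparison_speed": r.comparison_speed,
                         "comparison_tta": r.comparison_tta,
                         **m.__dict__})
    return pd.DataFrame(rows)


def outlier_report(metrics: pd.DataFrame,
                   cfg: OutlierConfig | None = None) -> dict:
    """Per-feature and overall flagged-data-point fractions (per observer).

    Mirrors reporting removals as a share of data points (feature values),
    not whole trials.
    """
    cfg = cfg or OutlierConfig()
    flagged = 0
    total = 0
    per_feature: dict[str, int] = {c: 0 for c in FEATURE_COLUMNS}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _pid, grp in metrics.groupby("participant_id", sort=False):
            for col in FEATURE_COLUMNS:
                vals = grp[col].to_numpy(dtype=float)
                fin = np.isfinite(vals)
                total += int(fin.sum())
                if fin.sum() < 3 or np.nanstd(vals) == 0:
                    continue
                keep = mad_outlier_filter(
                    vals, cfg, asymmetric=col in cfg.asymmetric_metrics)
                n_flag = int((~keep & fin).sum())
                flagged += n_flag
                per_feature[col] += n_flag
    return {"fraction_flagged": flagged / max(total, 1),
            "per_feature": per_feature, "n_data_points": total}


def remove_outliers(metrics: pd.DataFrame,
                    cfg: OutlierConfig | None = None) -> pd.DataFrame:
    """Per-observer MAD filtering of the feature columns.

    Count/amplitude features use the double-MAD criterion (skewed); the
    remaining features the symmetric criterion.  A row is dropped when any
    feature is flagged for that observer.
    """
    cfg = cfg or OutlierConfig()
    keep_all = np.ones(len(metrics), dtype=bool)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        for _pid, grp in metrics.groupby("participant_id", sort=False):
            idx = grp.index.to_numpy()
            for col in FEATURE_COLUMNS:
                vals = grp[col].to_numpy(dtype=float)
                if np.isfinite(vals).sum() < 3 or np.nanstd(vals) == 0:
                    continue
                keep = mad_outlier_filter(
                    vals, cfg, asymmetric=col in cfg.asymmetric_metrics)
                keep_all[metrics.index.get_indexer(idx)] &= keep
    return metrics[keep_all]
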