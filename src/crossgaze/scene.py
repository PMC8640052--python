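"""Virtual road-crossing scene: geometry, design grid, trajectories and AOIs.

The simulated scenario is a pedestrian standing 0.64 m from the curb of a
single-lane road (width 3.36 m), watching a car approach at constant speed.
The stimulus is rendered by a pinhole camera onto a 1280x1024 image shown on
a flat screen that spans roughly 30 x 25 visual degrees at a 66 cm viewing
distance.

Coordinate convention (right-handed, observer's eye at the origin):

* ``+Z`` up,
* ``+Y`` along the road, pointing away from the observer towards where the
  vehicle comes from,
* ``+X`` across the road.

The road centerline lies at lateral offset ``x_c = curb_gap + road_width/2``;
the stopping line is abeam of the observer (``Y = 0``); the tracked vehicle
point is the front-plane center at height ``vehicle_height/2``.
``approach_side == "left"`` mirrors the X axis.  Speeds are km/h at the
interface and m/s internally; all angles are degrees.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

KMH_TO_MS = 1.0 / 3.6

__all__ = [
    "SceneConfig",
    "DesignGrid",
    "TrialSpec",
    "Trajectory",
    "AoiBox",
    "start_distance",
    "make_trajectory",
    "trajectory",
    "world_to_view_angles",
    "view_angles_to_unit",
    "angular_size",
    "view_to_screen",
    "screen_to_view",
    "screen_to_unit",
    "make_design",
    "vehicle_aoi",
    "aoi_center_path",
]


@dataclass(frozen=True)
class SceneConfig:
    """Scene geometry and display parameters (lengths in m, angles in deg)."""

    road_width: float = 3.36
    vehicle_length: float = 4.53
    vehicle_width: float = 1.82
    vehicle_height: float = 1.47
    eye_height: float = 1.6
    curb_gap: float = 0.64
    display_duration: float = 3.0
    post_offset_duration: float = 2.0
    viewing_distance: float = 0.66
    screen_extent: tuple[float, float] = (30.0, 25.0)
    image_size: tuple[int, int] = (1280, 1024)
    camera_vertical_fov: float = 55.0
    # crossing AOI: screen-degree rectangle covering the crossing area below
    # the horizon (center_x, center_y, half_width, half_height)
    crossing_aoi_extent: tuple[float, float, float, float] = (0.0, -6.0, 10.0, 5.0)
    aoi_margin: float = 0.25

    def __post_init__(self) -> None:
        for name in ("road_width", "vehicle_length", "vehicle_width",
                     "vehicle_height", "eye_height", "curb_gap",
                     "viewing_distance"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if self.display_duration <= 0:
            raise ValueError("display_duration must be > 0")
        if not (10.0 < self.camera_vertical_fov < 120.0):
            raise ValueError("camera_vertical_fov must lie in (10, 120) degrees")

    @property
    def lateral_offset(self) -> float:
        """Distance from the eye to the road centerline (m)."""
        return self.curb_gap + self.road_width / 2.0

    @property
    def camera_horizontal_fov(self) -> float:
        """Horizontal FOV implied by the vertical FOV and image aspect."""
        w, h = self.image_size
        half = np.arctan(np.tan(np.radians(self.camera_vertical_fov / 2)) * w / h)
        return float(np.degrees(2 * half))


@dataclass(frozen=True)
class DesignGrid:
    """The 9 x 9 comparison grid plus the fixed standard stimulus."""

    speed_levels: tuple[float, ...] = tuple(float(s) for s in range(10, 100, 10))
    tta_levels: tuple[float, ...] = tuple(round(1.44 + 0.4 * i, 2) for i in range(9))
    standard_speed: float = 50.0
    standard_tta: float = 3.04
    n_blocks: int = 3

    def __post_init__(self) -> None:
        if len(self.speed_levels) != 9 or len(self.tta_levels) != 9:
            raise ValueError("design grid must have 9 speed and 9 TTA levels")
        if self.standard_speed not in self.speed_levels:
            raise ValueError("standard speed must be a grid level")
        if not any(abs(self.standard_tta - t) < 1e-9 for t in self.tta_levels):
            raise ValueError("standard TTA must be a grid level")

    @property
    def cells(self) -> list[tuple[float, float]]:
        return list(itertools.product(self.speed_levels, self.tta_levels))


@dataclass(frozen=True)
class TrialSpec:
    participant_id: str
    task: str  # "speed" | "tta"
    block: int
    trial_index: int
    comparison_speed: float  # km/h
    comparison_tta: float  # s
    standard_first: bool
    approach_side: str  # "left" | "right"

    def __post_init__(self) -> None:
        if self.task not in ("speed", "tta"):
            raise ValueError("task must be 'speed' or 'tta'")
        if self.approach_side not in ("left", "right"):
            raise ValueError("approach_side must be 'left' or 'right'")


@dataclass
class Trajectory:
    """Constant-speed approach sampled at a fixed rate.

    ``along_road_distance`` is the distance from the vehicle front edge to the
    stopping line, d(t) = d_start - v t, extrapolated past display offset;
    ``visible`` marks the 3 s display interval.
    """

    times: np.ndarray  # s from interval onset
    along_road_distance: np.ndarray  # m
    world_points: np.ndarray  # (n, 3) front-plane center in the eye frame
    visible: np.ndarray  # bool
    speed_ms: float
    remaining_tta: float
    approach_side: str


@dataclass(frozen=True)
class AoiBox:
    center: tuple[float, float]  # screen degrees
    half_width: float
    half_height: float
    kind: str  # "vehicle" | "crossing"

    def contains(self, x: float, y: float) -> bool:
        return (abs(x - self.center[0]) <= self.half_width
                and abs(y - self.center[1]) <= self.half_height)

    @property
    def area(self) -> float:
        return 4.0 * self.half_width * self.half_height


def start_distance(speed_ms: float, remaining_tta: float,
                   display_duration: float = 3.0) -> float:
    """Front-edge distance to the stopping line at interval onset (m).

    With a fixed display time the vehicle must start at
    ``v * (display + remaining_tta)`` so that it is ``v * remaining_tta`` from
    the stopping line when it disappears.
    """
    if speed_ms <= 0 or remaining_tta <= 0 or display_duration <= 0:
        raise ValueError("speed, remaining TTA and display duration must be positive")
    return speed_ms * (display_duration + remaining_tta)


def make_trajectory(speed_kmh: float, remaining_tta: float, approach_side: str,
                    scene: SceneConfig, sample_rate: float = 1000.0) -> Trajectory:
    """Sample the constant-speed approach (display plus post-offset period)."""
    if sample_rate < 1.0:
        raise ValueError("sample_rate must be at least 1 Hz")
    v = speed_kmh * KMH_TO_MS
    d_start = start_distance(v, remaining_tta, scene.display_duration)
    if d_start - v * scene.display_duration <= 0:
        raise ValueError("infeasible trial: vehicle would cross the stopping "
                         "line before display offset")
    total = scene.display_duration + scene.post_offset_duration
    n = int(round(total * sample_rate))
    t = np.arange(n) / sample_rate
    d = d_start - v * t
    sign = 1.0 if approach_side == "right" else -1.0
    pts = np.column_stack([
        np.full(n, sign * scene.lateral_offset),
        d,
        np.full(n, scene.vehicle_height / 2.0 - scene.eye_height),
    ])
    visible = t < scene.display_duration
    return Trajectory(t, d, pts, visible, v, remaining_tta, approach_side)


def trajectory(trial: TrialSpec, scene: SceneConfig, sample_rate: float = 1000.0,
               interval: str = "comparison",
               grid: DesignGrid | None = None) -> Trajectory:
    """Trajectory of one interval of a trial (comparison by default)."""
    if interval == "comparison":
        speed, tta = trial.comparison_speed, trial.comparison_tta
    elif interval == "standard":
        g = grid or DesignGrid()
        speed, tta = g.standard_speed, g.standard_tta
    else:
        raise ValueError("interval must be 'standard' or 'comparison'")
    return make_trajectory(speed, tta, trial.approach_side, scene, sample_rate)


def world_to_view_angles(point: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Azimuth/elevation (deg) of a world point seen from the eye.

    Azimuth is measured from the road direction (+Y) towards +X, elevation
    from the horizontal plane.  Accepts a single point or an (n, 3) array.
    """
    p = np.asarray(point, dtype=float)
    single = p.ndim == 1
    p = np.atleast_2d(p)
    if np.any(np.all(p == 0.0, axis=1)):
        raise ValueError("cannot compute view angles of the zero vector")
    az = np.degrees(np.arctan2(p[:, 0], p[:, 1]))
    el = np.degrees(np.arctan2(p[:, 2], np.hypot(p[:, 0], p[:, 1])))
    if single:
        return float(az[0]), float(el[0])
    return az, el


def view_angles_to_unit(azimuth, elevation) -> np.ndarray:
    """Unit direction vectors from azimuth/elevation in degrees."""
    az = np.radians(np.asarray(azimuth, dtype=float))
    el = np.radians(np.asarray(elevation, dtype=float))
    return np.stack([np.cos(el) * np.sin(az),
                     np.cos(el) * np.cos(az),
                     np.sin(el)], axis=-1)


def angular_size(width: float, distance: float) -> float:
    """Visual angle (deg) subtended by an extent seen face-on at a distance."""
    if width <= 0 or distance <= 0:
        raise ValueError("width and distance must be positive")
    return float(np.degrees(2.0 * np.arctan(width / (2.0 * distance))))


def view_to_screen(azimuth, elevation, scene: SceneConfig):
    """Project view angles through the camera onto screen visual degrees.

    Pinhole projection with the configured vertical FOV onto the image plane,
    then conversion of image position to visual degrees for a flat screen
    spanning ``screen_extent`` at ``viewing_distance``.  Directions outside
    the camera frustum map to NaN (out of frame), not an exception.
    """
    az = np.radians(np.asarray(azimuth, dtype=float))
    el = np.radians(np.asarray(elevation, dtype=float))
    # camera-frame image-plane coordinates (camera looks along +Y)
    u = np.tan(az)
    v = np.tan(el) / np.cos(az)
    tan_h = np.tan(np.radians(scene.camera_horizontal_fov / 2))
    tan_v = np.tan(np.radians(scene.camera_vertical_fov / 2))
    out = (np.abs(u) > tan_h) | (np.abs(v) > tan_v) | (np.abs(az) >= np.pi / 2)
    # normalized image position in [-1, 1] -> physical screen position -> deg
    hx = np.radians(scene.screen_extent[0] / 2)
    hy = np.radians(scene.screen_extent[1] / 2)
    sx = np.degrees(np.arctan((u / tan_h) * np.tan(hx)))
    sy = np.degrees(np.arctan((v / tan_v) * np.tan(hy)))
    sx = np.where(out, np.nan, sx)
    sy = np.where(out, np.nan, sy)
    if np.ndim(azimuth) == 0 and np.ndim(elevation) == 0:
        return float(sx), float(sy)
    return sx, sy


def screen_to_view(screen_x, screen_y, scene: SceneConfig):
    """Inverse of :func:`view_to_screen` on its domain."""
    hx = np.radians(scene.screen_extent[0] / 2)
    hy = np.radians(scene.screen_extent[1] / 2)
    tan_h = np.tan(np.radians(scene.camera_horizontal_fov / 2))
    tan_v = np.tan(np.radians(scene.camera_vertical_fov / 2))
    u = np.tan(np.radians(np.asarray(screen_x, dtype=float))) / np.tan(hx) * tan_h
    v = np.tan(np.radians(np.asarray(screen_y, dtype=float))) / np.tan(hy) * tan_v
    az = np.arctan(u)
    el = np.arctan(v * np.cos(az))
    if np.ndim(screen_x) == 0 and np.ndim(screen_y) == 0:
        return float(np.degrees(az)), float(np.degrees(el))
    return np.degrees(az), np.degrees(el)


def screen_to_unit(screen_x, screen_y, scene: SceneConfig) -> np.ndarray:
    """Unit 3D directions in the *virtual world* frame for gaze samples.

    Inverts the camera projection, so angles here are commensurate with
    vehicle-trajectory vectors (used for pursuit gain).
    """
    az, el = screen_to_view(screen_x, screen_y, scene)
    return view_angles_to_unit(az, el)


def screen_to_eye_unit(screen_x, screen_y) -> np.ndarray:
    """Unit eye-rotation directions for screen-degree gaze samples.

    Physical frame of the observer looking at the flat screen: per-axis
    visual degrees map to a direction (tan sx, 1, tan sy), normalized.
    Saccade amplitudes are measured in this frame.
    """
    tx = np.tan(np.radians(np.asarray(screen_x, dtype=float)))
    ty = np.tan(np.radians(np.asarray(screen_y, dtype=float)))
    v = np.stack([tx, np.ones_like(tx), ty], axis=-1)
    return v / np.linalg.norm(v, axis=-1, keepdims=True)


def make_design(grid: DesignGrid, seed: int, participant_id: str = "p01",
                task: str = "speed") -> list[TrialSpec]:
    """Randomized trial list for one session: n_blocks x 81 trials.

    Every (speed, TTA) combination appears exactly once per block in
    seeded-random order; standard/comparison order is randomized per trial
    and the approach side alternates between trials (starting side seeded).
    """
    rng = np.random.default_rng(seed)
    sides = ("left", "right")
    start_side = int(rng.integers(2))
    trials: list[TrialSpec] = []
    idx = 0
    for block in range(grid.n_blocks):
        cells = grid.cells
        order = rng.permutation(len(cells))
        for j in order:
            speed, tta = cells[j]
            trials.append(TrialSpec(
                participant_id=participant_id,
                task=task,
                block=block,
                trial_index=idx,
                comparison_speed=speed,
                comparison_tta=tta,
                standard_first=bool(rng.integers(2)),
                approach_side=sides[(start_side + idx) % 2],
            ))
            idx += 1
    return trials


def design_to_frame(trials: list[TrialSpec]) -> pd.DataFrame:
    return pd.DataFrame([asdict(t) for t in trials])


def _front_plane_corners(d: float, side_sign: float, scene: SceneConfig) -> np.ndarray:
    xc = side_sign * scene.lateral_offset
    xs = (xc - scene.vehicle_width / 2, xc + scene.vehicle_width / 2)
    zs = (-scene.eye_height, scene.vehicle_height - scene.eye_height)
    return np.array([[x, d, z] for x in xs for z in zs])


def vehicle_aoi(trial: TrialSpec, t: float, scene: SceneConfig,
                grid: DesignGrid | None = None,
                interval: str = "comparison") -> AoiBox | None:
    """Dynamic vehicle AOI: projected front-plane bounding box plus margin.

    Returns ``None`` after the vehicle has disappeared (no-AOI marker).
    """
    if t >= scene.display_duration or t < 0:
        return None
    if interval == "comparison":
        speed, tta = trial.comparison_speed, trial.comparison_tta
    else:
        g = grid or DesignGrid()
        speed, tta = g.standard_speed, g.standard_tta
    v = speed * KMH_TO_MS
    d = start_distance(v, tta, scene.display_duration) - v * t
    sign = 1.0 if trial.approach_side == "right" else -1.0
    corners = _front_plane_corners(d, sign, scene)
    az, el = world_to_view_angles(corners)
    sx, sy = view_to_screen(az, el, scene)
    caz, cel = world_to_view_angles(
        np.array([sign * scene.lateral_offset, d,
                  scene.vehicle_height / 2 - scene.eye_height]))
    cx, cy = view_to_screen(caz, cel, scene)
    m = scene.aoi_margin
    half_w = (np.nanmax(sx) - np.nanmin(sx)) / 2 + m
    half_h = (np.nanmax(sy) - np.nanmin(sy)) / 2 + m
    return AoiBox(center=(cx, cy), half_width=float(half_w),
                  half_height=float(half_h), kind="vehicle")


def crossing_aoi(scene: SceneConfig) -> AoiBox:
    cx, cy, hw, hh = scene.crossing_aoi_extent
    return AoiBox(center=(cx, cy), half_width=hw, half_height=hh, kind="crossing")


def aoi_center_path(traj: Trajectory, scene: SceneConfig) -> np.ndarray:
    """Screen-degree path of the vehicle-AOI center over a trajectory.

    Past display offset the path extrapolates the (invisible) constant-speed
    approach, mirroring how an observer would project the target forward.
    """
    az, el = world_to_view_angles(traj.world_points)
    sx, sy = view_to_screen(az, el, scene)
    return np.column_stack([sx, sy])
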