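"""Trajectory metrics for the open field and the rotating-arena avoidance task.

The rotating arena ("Carousel maze") is an 82 cm diameter disc turning at
one revolution per minute while a 60-degree sector stays fixed relative to
the room; the animal must avoid the room-stable sector using room cues.
Entering the sector triggers a footshock at entrance onset and another one
for every further 900 ms of continuous occupancy.  Positions can be
expressed in the laboratory-fixed *room* frame or the disc-fixed *arena*
frame; the transform is a pure time-dependent rotation, so radial distance
from the arena center is preserved exactly.

The open field is a 70 x 70 cm box explored for 15 min; locomotion is the
path length of the (optionally median-smoothed) center-point trajectory and
anxiety-related behavior is indexed by time spent in a concentric center
zone (default a quarter of the floor area — the box never defines "center"
physically, so the fraction is configurable).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import medfilt

from .io_formats import Trajectory

__all__ = [
    "ArenaConfig",
    "OpenFieldConfig",
    "CarouselMetrics",
    "transform_frame",
    "path_length",
    "time_in_center",
    "detect_entrances",
    "count_shocks",
    "time_in_sector",
    "bin_metric",
    "carousel_metrics",
    "openfield_metrics",
]


@dataclass(frozen=True)
class ArenaConfig:
    """Rotating-arena geometry, rotation, avoided sector and shock rule."""

    radius: float = 41.0               # cm (82 cm diameter disc)
    rotation_period: float = 60.0      # s (1 rpm)
    rotation_ccw: bool = True          # direction unstated in the task, configurable
    sector_center_deg: float = 0.0     # room-frame azimuth of sector center
    sector_halfwidth_deg: float = 30.0 # 60-degree sector
    shock_interval: float = 0.9        # s between shocks while inside
    shock_current_mA: float = 0.4      # metadata only
    session_length: float = 1200.0     # s (20-min daily session)

    def __post_init__(self) -> None:
        if not 0 < self.sector_halfwidth_deg < 180:
            raise ValueError("sector halfwidth must be in (0, 180) degrees")
        if self.shock_interval <= 0:
            raise ValueError("shock_interval must be positive")


@dataclass(frozen=True)
class OpenFieldConfig:
    """Open-field box geometry and center-zone definition."""

    side: float = 70.0                 # cm
    center_zone_fraction: float = 0.25 # fraction of floor area counted as center
    session_length: float = 900.0      # s (15 min)

    def __post_init__(self) -> None:
        if not 0 < self.center_zone_fraction < 1:
            raise ValueError("center_zone_fraction must be in (0, 1)")

    @property
    def center_side(self) -> float:
        """Side of the concentric center square (cm)."""
        return self.side * np.sqrt(self.center_zone_fraction)


@dataclass
class CarouselMetrics:
    """Session-level avoidance metrics plus per-interval bins."""

    entrances: int
    shocks: int
    distance_room: float
    distance_arena: float
    time_in_sector: float
    entrance_intervals: list[tuple[float, float]]
    shock_times: np.ndarray
    per_interval: dict[str, np.ndarray] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if min(self.entrances, self.shocks) < 0 or self.time_in_sector < 0:
            raise ValueError("metrics must be non-negative")
        if self.time_in_sector > 0 and self.shocks < self.entrances:
            raise ValueError("each entrance delivers at least one shock")


def _rotation_angle(t: np.ndarray, arena: ArenaConfig) -> np.ndarray:
    sign = 1.0 if arena.rotation_ccw else -1.0
    return sign * 2.0 * np.pi * t / arena.rotation_period


def transform_frame(traj: Trajectory, arena: ArenaConfig, target: str) -> Trajectory:
    """Rotate a trajectory between room and arena frames.

    A disc-fixed point at arena azimuth ``phi`` appears in the room at
    ``phi + theta(t)`` with ``theta(t) = +/- 2*pi*t / rotation_period``, so
    arena->room rotates by ``+theta(t)`` and room->arena by ``-theta(t)``.
    The round trip is the identity and radii are preserved exactly.
    """
    if target not in ("room", "arena"):
        raise ValueError(f"target frame must be 'room' or 'arena', got {target!r}")
    if target == traj.frame:
        warnings.warn(f"trajectory already in {target!r} frame; no-op", stacklevel=2)
        return traj
    theta = _rotation_angle(traj.t, arena)
    if target == "arena":
        theta = -theta
    c, s = np.cos(theta), np.sin(theta)
    x = c * traj.x - s * traj.y
    y = s * traj.x + c * traj.y
    return Trajectory(traj.t.copy(), x, y, frame=target, likelihood=traj.likelihood)


def path_length(traj: Trajectory, smooth_win: int = 1, jitter_floor: float = 0.0) -> float:
    """Total distance moved (cm): sum of Euclidean steps after median
    smoothing, with steps below *jitter_floor* ignored (tracker-noise
    suppression)."""
    if len(traj) < 2:
        return 0.0
    x, y = traj.x, traj.y
    if smooth_win > 1:
        k = smooth_win if smooth_win % 2 else smooth_win + 1
        x = medfilt(x, k)
        y = medfilt(y, k)
    steps = np.hypot(np.diff(x), np.diff(y))
    return float(steps[steps >= jitter_floor].sum()) if jitter_floor > 0 else float(steps.sum())


def _sample_dwell(t: np.ndarray) -> np.ndarray:
    """Time owned by each sample: the interval to the next sample; the last
    sample owns the width of the preceding interval."""
    if len(t) < 2:
        return np.zeros(len(t))
    dt = np.diff(t)
    return np.append(dt, dt[-1])


def time_in_center(traj: Trajectory, cfg: OpenFieldConfig) -> float:
    """Seconds spent inside the concentric center square (box centered on 0)."""
    half = cfg.center_side / 2.0
    inside = (np.abs(traj.x) <= half) & (np.abs(traj.y) <= half)
    return float(_sample_dwell(traj.t)[inside].sum())


def _wrap_deg(a: np.ndarray) -> np.ndarray:
    return (np.asarray(a) + 180.0) % 360.0 - 180.0


def _in_sector(traj: Trajectory, arena: ArenaConfig) -> np.ndarray:
    az = np.degrees(np.arctan2(traj.y, traj.x))
    return np.abs(_wrap_deg(az - arena.sector_center_deg)) <= arena.sector_halfwidth_deg


def detect_entrances(
    traj: Trajectory,
    arena: ArenaConfig,
    min_outside: float = 0.0,
) -> list[tuple[float, float]]:
    """Maximal in-sector intervals of a room-frame trajectory.

    Each entrance is ``(enter_t, exit_t)`` with ``enter_t`` the first
    in-sector sample and ``exit_t`` the first out-of-sector sample after it
    (half-open).  Consecutive entrances separated by less than *min_outside*
    seconds are merged (hysteresis for tracker noise; default 0 = every
    sector exit ends an entrance).
    """
    if traj.frame != "room":
        raise ValueError("entrances are defined on room-frame trajectories")
    inside = _in_sector(traj, arena)
    if not inside.any():
        return []
    t = traj.t
    dwell = _sample_dwell(t)
    padded = np.concatenate(([False], inside, [False]))
    starts = np.flatnonzero(~padded[:-1] & padded[1:])
    ends = np.flatnonzero(padded[:-1] & ~padded[1:])  # index after last inside
    intervals = []
    for i0, i1 in zip(starts, ends):
        exit_t = t[i1] if i1 < len(t) else t[-1] + dwell[-1]
        intervals.append((float(t[i0]), float(exit_t)))
    if min_outside > 0 and len(intervals) > 1:
        merged = [intervals[0]]
        for enter, exit_ in intervals[1:]:
            if enter - merged[-1][1] < min_outside:
                merged[-1] = (merged[-1][0], exit_)
            else:
                merged.append((enter, exit_))
        intervals = merged
    return intervals


def count_shocks(
    entrances: list[tuple[float, float]],
    arena: ArenaConfig,
) -> tuple[int, np.ndarray]:
    """Shock count and times for a list of entrance intervals.

    One shock fires at entrance onset, then one every ``shock_interval``
    of continuous occupancy: a dwell of ``d`` seconds delivers one shock
    per ``k >= 0`` with ``k * shock_interval < d``.
    """
    times = []
    for enter, exit_ in entrances:
        d = exit_ - enter
        if d <= 0:
            continue
        n = int(np.floor((d - 1e-9) / arena.shock_interval)) + 1
        times.extend(enter + np.arange(n) * arena.shock_interval)
    times = np.asarray(times)
    return len(times), times


def time_in_sector(traj: Trajectory, arena: ArenaConfig) -> float:
    """Total seconds spent inside the room-frame avoided sector."""
    return float(sum(e - s for s, e in detect_entrances(traj, arena)))


def bin_metric(
    traj: Trajectory,
    bin_s: float,
    metric: str,
    arena: ArenaConfig | None = None,
    openfield: OpenFieldConfig | None = None,
    smooth_win: int = 1,
    jitter_floor: float = 0.0,
    min_outside: float = 0.0,
) -> np.ndarray:
    """Per-bin values of a session metric over half-open time bins.

    ``metric`` is one of ``distance``, ``entrances``, ``shocks``,
    ``center_time``; events/steps are assigned to the bin containing their
    start time, so binned distances sum to the total path length.
    ``bin_s`` must divide the session length (e.g. 5-min bins of a 20-min
    arena session, 1-min bins of a 15-min open-field session).
    """
    t0 = traj.t[0]
    session = traj.t[-1] - t0 + _sample_dwell(traj.t)[-1]
    n_bins = int(round(session / bin_s))
    if n_bins < 1 or abs(n_bins * bin_s - session) > max(2.0 * np.median(np.diff(traj.t)), 1e-9):
        raise ValueError(
            f"bin width {bin_s} s does not divide the {session:.3f} s session"
        )
    edges = t0 + np.arange(n_bins + 1) * bin_s
    out = np.zeros(n_bins)

    def _accumulate(event_t: np.ndarray, weights: np.ndarray | None = None) -> None:
        idx = np.clip(np.searchsorted(edges, event_t, side="right") - 1, 0, n_bins - 1)
        np.add.at(out, idx, 1.0 if weights is None else weights)

    if metric == "distance":
        x, y = traj.x, traj.y
        if smooth_win > 1:
            k = smooth_win if smooth_win % 2 else smooth_win + 1
            x, y = medfilt(x, k), medfilt(y, k)
        steps = np.hypot(np.diff(x), np.diff(y))
        if jitter_floor > 0:
            steps = np.where(steps >= jitter_floor, steps, 0.0)
        _accumulate(traj.t[:-1], steps)
    elif metric == "entrances":
        if arena is None:
            raise ValueError("metric 'entrances' needs an ArenaConfig")
        ent = detect_entrances(traj, arena, min_outside)
        if ent:
            _accumulate(np.array([e[0] for e in ent]))
    elif metric == "shocks":
        if arena is None:
            raise ValueError("metric 'shocks' needs an ArenaConfig")
        ent = detect_entrances(traj, arena, min_outside)
        _, times = count_shocks(ent, arena)
        if len(times):
            _accumulate(times)
    elif metric == "center_time":
        if openfield is None:
            raise ValueError("metric 'center_time' needs an OpenFieldConfig")
        half = openfield.center_side / 2.0
        inside = (np.abs(traj.x) <= half) & (np.abs(traj.y) <= half)
        _accumulate(traj.t[inside], _sample_dwell(traj.t)[inside])
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return out


def carousel_metrics(
    traj: Trajectory,
    arena: ArenaConfig,
    bin_s: float = 300.0,
    smooth_win: int = 1,
    jitter_floor: float = 0.0,
    min_outside: float = 0.0,
) -> CarouselMetrics:
    """All avoidance metrics for one room-frame arena session.

    ``distance_arena`` (locomotion net of passive disc transport, computed
    in the arena frame) is the headline distance; the room-frame value is
    reported alongside.  Default binning is 5-min intervals.
    """
    if traj.frame != "room":
        raise ValueError("carousel metrics expect a room-frame trajectory")
    entrances = detect_entrances(traj, arena, min_outside)
    n_shocks, shock_t = count_shocks(entrances, arena)
    traj_arena = transform_frame(traj, arena, "arena")
    per_interval = {
        m: bin_metric(traj, bin_s, m, arena=arena, smooth_win=smooth_win,
                      jitter_floor=jitter_floor, min_outside=min_outside)
        for m in ("distance", "entrances", "shocks")
    }
    return CarouselMetrics(
        entrances=len(entrances),
        shocks=n_shocks,
        distance_room=path_length(traj, smooth_win, jitter_floor),
        distance_arena=path_length(traj_arena, smooth_win, jitter_floor),
        time_in_sector=float(sum(e - s for s, e in entrances)),
        entrance_intervals=entrances,
        shock_times=shock_t,
        per_interval=per_interval,
    )


def openfield_metrics(
    traj: Trajectory,
    cfg: OpenFieldConfig,
    bin_s: float = 60.0,
    smooth_win: int = 1,
    jitter_floor: float = 0.0,
) -> dict:
    """Open-field locomotion and center-time metrics with 1-min bins."""
    return {
        "distance": path_length(traj, smooth_win, jitter_floor),
        "center_time": time_in_center(traj, cfg),
        "distance_bins": bin_metric(traj, bin_s, "distance",
                                    smooth_win=smooth_win, jitter_floor=jitter_floor),
        "center_time_bins": bin_metric(traj, bin_s, "center_time", openfield=cfg),
    }
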