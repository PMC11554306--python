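"""Hole-check (active sensing) detection and spatial statistics.

A hole check is a brief visit in which the mouse slows down with its nose
at a hole to inspect it.  Two complementary detectors run in sequence on
the smoothed speed trace:

method 1 (minimum-velocity criterion), all four conditions at once:
  (i) nose within 3 cm of a hole; (ii) speed below 20% of the trial
  maximum; (iii) speed at a local minimum; (iv) speed dropped by at least
  5 cm/s from the preceding local maximum to reach that minimum.

method 2 (slow-down criterion) adds events at downward crossings of the
20% threshold while within 3 cm of a hole, skipping anything already
claimed by method 1 on the same hole within a merge window.  A visit in
which the speed sits below the threshold before and after never crosses
it, so neither method fires — the detectors' documented blind spot.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .arena import ArenaLayout
from .trajectory import Trajectory, instantaneous_speed

PROXIMITY_RADIUS = 3.0   # cm
SPEED_FRACTION = 0.2     # of trial max
MIN_DROP = 5.0           # cm/s
MERGE_WINDOW = 0.5       # s, same-hole dedup
NEAR_RADIUS = 20.0       # cm, "near target"


@dataclass(frozen=True)
class HoleCheckEvent:
    time_index: int
    time_s: float
    hole_id: int
    x: float
    y: float
    method: int


def _nearby_hole(layout: ArenaLayout, tree: cKDTree, xy: np.ndarray, radius: float):
    """Per-sample nearest hole id within ``radius`` (or -1)."""
    d, idx = tree.query(xy, distance_upper_bound=radius)
    hole = np.where(np.isfinite(d), idx, -1)
    out = np.full(len(xy), -1, dtype=int)
    ok = hole >= 0
    out[ok] = layout.hole_ids[hole[ok].astype(int)]
    return out


def _local_minima(speed: np.ndarray) -> np.ndarray:
    """Strict 3-sample local minima of the (smoothed) speed series."""
    if len(speed) < 3:
        return np.zeros(len(speed), dtype=bool)
    mins = np.zeros(len(speed), dtype=bool)
    mins[1:-1] = (speed[1:-1] < speed[:-2]) & (speed[1:-1] < speed[2:])
    return mins


def _drop_from_preceding_max(speed: np.ndarray, minima_idx: np.ndarray) -> np.ndarray:
    """Speed drop from the last local maximum (or series start) before each minimum."""
    drops = np.empty(len(minima_idx))
    for k, i in enumerate(minima_idx):
        j = i
        while j > 0 and speed[j - 1] >= speed[j]:
            j -= 1
        # continue back to the top of the preceding rise
        peak = speed[j]
        drops[k] = peak - speed[i]
    return drops


def detect_method1(
    traj: Trajectory,
    layout: ArenaLayout,
    speed: np.ndarray,
    proximity_radius: float = PROXIMITY_RADIUS,
    speed_fraction: float = SPEED_FRACTION,
    min_drop: float = MIN_DROP,
) -> list[HoleCheckEvent]:
    """Minimum-velocity hole-check detector (the four simultaneous conditions)."""
    if len(speed) != len(traj):
        raise ValueError("speed series must align with the trajectory")
    if len(traj) < 3:
        return []
    tree = cKDTree(layout.holes)
    holes = _nearby_hole(layout, tree, traj.xy, proximity_radius)
    vmax = float(speed.max())
    thr = speed_fraction * vmax
    mins = _local_minima(speed)
    cand = np.flatnonzero(mins & (speed < thr) & (holes >= 0))
    if cand.size == 0:
        return []
    drops = _drop_from_preceding_max(speed, cand)
    events = []
    for i, dr in zip(cand, drops):
        if dr >= min_drop:
            # one event per hole visit: merge repeated minima inside a dwell
            if events and events[-1].hole_id == holes[i] and traj.t[i] - events[-1].time_s <= MERGE_WINDOW:
                continue
            events.append(
                HoleCheckEvent(
                    time_index=int(i),
                    time_s=float(traj.t[i]),
                    hole_id=int(holes[i]),
                    x=float(traj.x[i]),
                    y=float(traj.y[i]),
                    method=1,
                )
            )
    return events


def detect_method2(
    traj: Trajectory,
    layout: ArenaLayout,
    speed: np.ndarray,
    existing: list[HoleCheckEvent],
    proximity_radius: float = PROXIMITY_RADIUS,
    speed_fraction: float = SPEED_FRACTION,
    merge_window: float = MERGE_WINDOW,
) -> list[HoleCheckEvent]:
    """Slow-down detector: downward 20%-threshold crossings near a hole.

    Run after method 1; crossings within ``merge_window`` seconds of an
    existing event on the same hole are not duplicated.
    """
    if len(speed) != len(traj):
        raise ValueError("speed series must align with the trajectory")
    if len(traj) < 2:
        return []
    tree = cKDTree(layout.holes)
    holes = _nearby_hole(layout, tree, traj.xy, proximity_radius)
    thr = speed_fraction * float(speed.max())
    crossing = np.flatnonzero((speed[:-1] >= thr) & (speed[1:] < thr)) + 1
    events = []
    for i in crossing:
        if holes[i] < 0:
            continue
        t_i = float(traj.t[i])
        dup = any(
            ev.hole_id == holes[i] and abs(ev.time_s - t_i) <= merge_window
            for ev in existing + events
        )
        if not dup:
            events.append(
                HoleCheckEvent(
                    time_index=int(i),
                    time_s=t_i,
                    hole_id=int(holes[i]),
                    x=float(traj.x[i]),
                    y=float(traj.y[i]),
                    method=2,
                )
            )
    return events


def detect_checks(
    traj: Trajectory,
    layout: ArenaLayout,
    smoothing_window: int = 5,
    **kwargs,
) -> list[HoleCheckEvent]:
    """Both detectors in sequence, events merged and sorted by time."""
    if len(traj) < 3:
        return []
    speed = instantaneous_speed(traj, smoothing_window=smoothing_window)
    m1 = detect_method1(traj, layout, speed, **{k: v for k, v in kwargs.items() if k in ("proximity_radius", "speed_fraction", "min_drop")})
    m2 = detect_method2(traj, layout, speed, m1, **{k: v for k, v in kwargs.items() if k in ("proximity_radius", "speed_fraction", "merge_window")})
    return sorted(m1 + m2, key=lambda e: e.time_index)


def events_to_frame(events: list[HoleCheckEvent], **meta) -> pd.DataFrame:
    df = pd.DataFrame(
        [
            {"time_index": e.time_index, "time_s": e.time_s, "hole_id": e.hole_id,
             "x_cm": e.x, "y_cm": e.y, "method": e.method}
            for e in events
        ],
        columns=["time_index", "time_s", "hole_id", "x_cm", "y_cm", "method"],
    )
    for k, v in meta.items():
        df[k] = v
    return df


# --- spatial statistics -------------------------------------------------


@dataclass(frozen=True)
class CheckSpatialStats:
    """Per-hole check frequencies and (restricted) moments of their positions.

    ``P`` maps hole_id -> normalized check frequency.  The restricted
    moments use only checks within ``near_radius`` of the target; sigma_D
    = sqrt(lambda1 + lambda2) of the restricted covariance is the spatial
    uncertainty that scales the TEV magnitude error.
    """

    n_events: int
    P: dict
    mean: np.ndarray | None
    covariance: np.ndarray | None
    eigvals: np.ndarray | None
    n_restricted: int
    restricted_mean: np.ndarray | None
    restricted_covariance: np.ndarray | None
    sigma_D: float


def _moments(points: np.ndarray):
    mean = points.mean(axis=0)
    centered = points - mean
    cov = centered.T @ centered / len(points)
    return mean, cov


def spatial_stats(
    events: list[HoleCheckEvent],
    layout: ArenaLayout,
    target_xy,
    near_radius: float = NEAR_RADIUS,
) -> CheckSpatialStats:
    """Normalized per-hole frequencies, spatial moments, restricted moments.

    Each event contributes its hole's coordinates; weighting hole positions
    by per-hole frequency is identical to averaging over the event list.
    Zero events return an empty-stats marker rather than dividing by zero.
    """
    if not events:
        return CheckSpatialStats(
            n_events=0, P={}, mean=None, covariance=None, eigvals=None,
            n_restricted=0, restricted_mean=None, restricted_covariance=None,
            sigma_D=float("nan"),
        )
    target_xy = np.asarray(target_xy, dtype=float)
    ids = np.array([e.hole_id for e in events])
    uniq, counts = np.unique(ids, return_counts=True)
    P = {int(h): float(c) / len(events) for h, c in zip(uniq, counts)}
    pts = np.stack([layout.hole_xy(int(h)) for h in ids])
    mean, cov = _moments(pts)
    eig = np.linalg.eigvalsh(cov)
    near = np.linalg.norm(pts - target_xy, axis=1) <= near_radius
    if near.any():
        rmean, rcov = _moments(pts[near])
        sigma_d = float(np.sqrt(np.linalg.eigvalsh(rcov).sum()))
    else:
        rmean, rcov, sigma_d = None, None, float("nan")
    return CheckSpatialStats(
        n_events=len(events), P=P, mean=mean, covariance=cov, eigvals=eig,
        n_restricted=int(near.sum()), restricted_mean=rmean,
        restricted_covariance=rcov, sigma_D=sigma_d,
    )


# --- density profiles ---------------------------------------------------


def _disc_intersection_area(d: float, r: float, R: float) -> float:
    """Area of the intersection of discs with radii r, R at center distance d."""
    if d >= r + R:
        return 0.0
    if d <= abs(R - r):
        rr = min(r, R)
        return np.pi * rr * rr
    a = r * r * np.arccos((d * d + r * r - R * R) / (2 * d * r))
    b = R * R * np.arccos((d * d + R * R - r * r) / (2 * d * R))
    c = 0.5 * np.sqrt((-d + r + R) * (d + r - R) * (d - r + R) * (d + r + R))
    return float(a + b - c)


@dataclass(frozen=True)
class DensityProfile:
    half1_per_m: float
    half2_per_m: float
    near_count: int
    far_count: int
    near_area_cm2: float
    far_area_cm2: float
    near_per_cm2: float
    far_per_cm2: float
    distances_to_target_cm: np.ndarray


def density_profiles(
    events: list[HoleCheckEvent],
    traj: Trajectory,
    target_xy,
    arena_radius: float,
    near_radius: float = NEAR_RADIUS,
) -> DensityProfile:
    """Temporal-half check densities and near/far per-area densities.

    The trial is split into two halves of equal duration; each half's
    density is checks per meter traveled in that half.  "Near" is the disc
    of ``near_radius`` around the target clipped to the arena; "far" is the
    rest of the arena.
    """
    total = traj.path_length()
    if total <= 0:
        raise ValueError("zero traveled distance")
    target_xy = np.asarray(target_xy, dtype=float)
    t_mid = traj.t[0] + traj.duration / 2.0
    cum = traj.cumulative_length()
    i_mid = int(np.searchsorted(traj.t, t_mid))
    len1 = cum[min(i_mid, len(cum) - 1)]
    len2 = total - len1
    n1 = sum(1 for e in events if e.time_s < t_mid)
    n2 = len(events) - n1
    d_center = float(np.hypot(*target_xy))
    near_area = _disc_intersection_area(d_center, near_radius, arena_radius)
    far_area = np.pi * arena_radius**2 - near_area
    dists = np.array([np.hypot(e.x - target_xy[0], e.y - target_xy[1]) for e in events])
    near_count = int((dists <= near_radius).sum())
    far_count = len(events) - near_count
    return DensityProfile(
        half1_per_m=n1 / (len1 / 100.0) if len1 > 0 else np.nan,
        half2_per_m=n2 / (len2 / 100.0) if len2 > 0 else np.nan,
        near_count=near_count,
        far_count=far_count,
        near_area_cm2=near_area,
        far_area_cm2=far_area,
        near_per_cm2=near_count / near_area if near_area > 0 else np.nan,
        far_per_cm2=far_count / far_area if far_area > 0 else np.nan,
        distances_to_target_cm=dists,
    )


def count_entropy(counts) -> float:
    """Plug-in Shannon entropy (nats) of an across-mice count distribution.

    Identical counts give 0; counts uniform over k distinct values give
    log k.
    """
    counts = np.asarray(counts)
    if counts.size == 0:
        return float("nan")
    _, freq = np.unique(counts, return_counts=True)
    p = freq / freq.sum()
    return float(-np.sum(p * np.log(p)))
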