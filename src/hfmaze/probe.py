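"""Probe-trial analyses: search bias, REL arrival, randomized controls.

Probe trials contain no food; where the animal concentrates its search
reads out its spatial memory.  Search bias totals the occupancy of a
30 x 30 cm square around the target versus the squares at the target's
rotationally equivalent locations (RELs) in the other three quadrants over
the first two minutes.  The randomized-piece control re-measures any trial
metric on random sub-trajectories whose endpoints match a reference
separation (e.g. the B-to-A distance), giving a chance level for the
B-to-A shortcut comparison.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np

from .arena import quadrant_of, rel_of
from .errors import InsufficientPathError
from .trajectory import Trajectory

DEFAULT_WINDOW = 120.0          # s
DEFAULT_SQUARE_HALF_WIDTH = 15.0  # cm (30 x 30 square)
DEFAULT_CRITERION_RADIUS = 5.0  # cm, REL arrival
DEFAULT_N_PIECES = 10


@dataclass(frozen=True)
class ProbeBias:
    window_s: float
    square_half_width_cm: float
    percent_time_target_square: float
    percent_time_rel_squares: tuple  # at rotations 90, 180, 270
    percent_time_quadrants: tuple    # quadrants 1..4


def _window_slice(traj: Trajectory, window: float) -> Trajectory:
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    if traj.duration < window:
        warnings.warn(
            f"probe trajectory shorter ({traj.duration:.1f} s) than the "
            f"{window:.0f} s window; using available duration"
        )
    stop = int(np.searchsorted(traj.t, traj.t[0] + window, side="right"))
    return traj.slice(0, max(stop, 1))


def search_bias(
    probe_traj: Trajectory,
    target_xy,
    layout=None,
    window: float = DEFAULT_WINDOW,
    square_half_width: float = DEFAULT_SQUARE_HALF_WIDTH,
) -> ProbeBias:
    """Occupancy of the target square vs. its three REL squares.

    Percentages are of samples within the first ``window`` seconds (the
    sampling is uniform, so sample shares equal time shares).  Quadrant
    occupancies use the half-open sector rule and always sum to 100.
    """
    part = _window_slice(probe_traj, window)
    pts = part.xy
    target_xy = np.asarray(target_xy, dtype=float)
    centers = [target_xy] + [rel_of(target_xy, d) for d in (90, 180, 270)]
    shares = []
    for c in centers:
        inside = (np.abs(pts[:, 0] - c[0]) <= square_half_width) & (
            np.abs(pts[:, 1] - c[1]) <= square_half_width
        )
        shares.append(100.0 * inside.mean())
    quads = np.array([quadrant_of(p) for p in pts])
    qshare = tuple(100.0 * np.mean(quads == q) for q in (1, 2, 3, 4))
    return ProbeBias(
        window_s=window,
        square_half_width_cm=square_half_width,
        percent_time_target_square=shares[0],
        percent_time_rel_squares=tuple(shares[1:]),
        percent_time_quadrants=qshare,
    )


def rel_arrival(
    traj: Trajectory, rel_point, criterion_radius: float = DEFAULT_CRITERION_RADIUS
):
    """First passage within ``criterion_radius`` of the REL point.

    Returns (reached, latency_s); latency is NaN when never reached.
    """
    rel_point = np.asarray(rel_point, dtype=float)
    d = np.hypot(traj.x - rel_point[0], traj.y - rel_point[1])
    hit = np.flatnonzero(d <= criterion_radius)
    if hit.size == 0:
        return False, float("nan")
    return True, float(traj.t[hit[0]] - traj.t[0])


def randomized_piece_control(
    traj: Trajectory,
    separation: float,
    metric,
    n_pieces: int = DEFAULT_N_PIECES,
    seed: int = 0,
    tolerance: float = 2.0,
    max_attempts_per_piece: int = 20_000,
) -> tuple[float, list[float]]:
    """Chance level of ``metric`` from random same-separation sub-trajectories.

    Draws ``n_pieces`` random point pairs whose straight-line separation
    matches ``separation`` within ``tolerance`` cm, evaluates the metric on
    each sub-trajectory, and averages.  Raises
    :class:`InsufficientPathError` when no qualifying pair can be found.
    """
    rng = np.random.default_rng(seed)
    n = len(traj)
    if n < 2:
        raise InsufficientPathError("trajectory too short for piece extraction")
    pts = traj.xy
    values = []
    for _ in range(n_pieces):
        found = False
        for _ in range(max_attempts_per_piece):
            i, j = rng.integers(0, n, size=2)
            if i == j:
                continue
            i, j = (int(min(i, j)), int(max(i, j)))
            if abs(np.linalg.norm(pts[j] - pts[i]) - separation) <= tolerance:
                values.append(float(metric(traj.slice(i, j + 1))))
                found = True
                break
        if not found:
            raise InsufficientPathError(
                f"no point pair at separation {separation:.1f} +/- {tolerance} cm"
            )
    return float(np.mean(values)), values


def distance_to_point_vs_chance(
    traj: Trajectory,
    point,
    arena_radius: float,
    n_random: int = 1000,
    seed: int = 0,
):
    """Mean trajectory-to-point distance against a uniform-point chance level.

    The chance distribution evaluates the same statistic for ``n_random``
    points drawn uniformly over the arena disc.  Returns (observed mean,
    chance array, percentile of the observed value in the chance
    distribution).
    """
    point = np.asarray(point, dtype=float)
    observed = float(np.hypot(traj.x - point[0], traj.y - point[1]).mean())
    rng = np.random.default_rng(seed)
    r = arena_radius * np.sqrt(rng.uniform(size=n_random))
    th = rng.uniform(0, 2 * np.pi, size=n_random)
    px, py = r * np.cos(th), r * np.sin(th)
    chance = np.hypot(traj.x[:, None] - px[None, :], traj.y[:, None] - py[None, :]).mean(axis=0)
    percentile = float(100.0 * np.mean(chance < observed))
    return observed, chance, percentile
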