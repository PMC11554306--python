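"""Arena geometry: hole layout, rotational symmetry, frame alignment.

The arena is a circular open field (default radius 60 cm) with 100 small
holes, 25 per quadrant, whose pattern is invariant under rotations by
multiples of 90 degrees about the center.  One entrance sits on the wall in
each quadrant.  All analyses run in a common reference frame: origin at the
arena center, units cm, the aligned start at (0, +radius), counter-clockwise
rotations positive.  Entrance q lies at angle 90 - (q-1)*90 degrees, so that
rotating a quadrant-q trajectory counter-clockwise by (q-1)*90 degrees
brings its start onto the aligned start.

A hole at (x, y) has a rotationally equivalent location (REL) in each other
quadrant: the image of (x, y) under rotation by 90/180/270 degrees about
the center.  A mouse navigating by self-motion cues from a rotated entrance
heads to the REL of its trained target rather than the target itself.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .errors import (
    InvalidRotationError,
    NoQualifyingHoleError,
    OutOfArenaError,
    PackingInfeasibleError,
)

DEFAULT_RADIUS = 60.0
DEFAULT_HOLES_PER_QUADRANT = 25
DEFAULT_MIN_SPACING = 8.0
DEFAULT_WALL_MARGIN = 3.0
DEFAULT_CAPTURE_RADIUS = 1.5


def _rotation_matrix(deg: float) -> np.ndarray:
    th = np.deg2rad(deg)
    c, s = np.cos(th), np.sin(th)
    return np.array([[c, -s], [s, c]])


def entrance_angle_deg(quadrant: int) -> float:
    """Wall angle of entrance ``quadrant`` (1..4) in the common frame."""
    if quadrant not in (1, 2, 3, 4):
        raise ValueError(f"entrance quadrant must be 1..4, got {quadrant}")
    return 90.0 - (quadrant - 1) * 90.0


def quadrant_of(point) -> int:
    """Quadrant index (1..4) of a point, by half-open 90-degree sectors.

    Sector q is centered on entrance q; the boundary at +45 degrees from a
    sector center belongs to the next quadrant (half-open rule).
    """
    x, y = float(point[0]), float(point[1])
    ang = np.rad2deg(np.arctan2(y, x))
    d = (90.0 - ang) % 360.0
    return int(np.floor((d + 45.0) / 90.0)) % 4 + 1


@dataclass(frozen=True)
class ArenaLayout:
    """Hole coordinates, entrances and capture geometry of the arena.

    ``holes`` is an (n, 2) float array ordered by ``hole_ids``.
    """

    radius: float
    holes: np.ndarray
    hole_ids: np.ndarray
    hole_capture_radius: float = DEFAULT_CAPTURE_RADIUS
    symmetry_order: int = 4
    min_spacing: float = DEFAULT_MIN_SPACING
    wall_margin: float = DEFAULT_WALL_MARGIN

    @property
    def entrances(self) -> np.ndarray:
        """(4, 2) entrance positions on the wall, one per quadrant."""
        angs = np.deg2rad([entrance_angle_deg(q) for q in (1, 2, 3, 4)])
        return self.radius * np.column_stack([np.cos(angs), np.sin(angs)])

    @property
    def n_holes(self) -> int:
        return len(self.hole_ids)

    def entrance(self, quadrant: int) -> np.ndarray:
        return self.entrances[quadrant - 1]

    def hole_xy(self, hole_id: int) -> np.ndarray:
        idx = np.flatnonzero(self.hole_ids == hole_id)
        if idx.size == 0:
            raise KeyError(f"no hole with id {hole_id}")
        return self.holes[idx[0]]

    def wall_distance(self, point) -> float:
        return self.radius - float(np.hypot(point[0], point[1]))

    def validate(self, atol: float = 1e-6) -> None:
        """Check all layout invariants; raise ValueError on violation."""
        r = np.hypot(self.holes[:, 0], self.holes[:, 1])
        if not np.all(r < self.radius):
            raise ValueError("hole outside arena disc")
        quads = np.array([quadrant_of(p) for p in self.holes])
        counts = np.bincount(quads, minlength=5)[1:]
        if not np.all(counts == counts[0]):
            raise ValueError(f"unequal holes per quadrant: {counts}")
        d = np.linalg.norm(self.holes[:, None] - self.holes[None, :], axis=-1)
        np.fill_diagonal(d, np.inf)
        if d.min() < self.min_spacing - atol:
            raise ValueError(f"hole spacing {d.min():.3f} < {self.min_spacing}")
        for deg in (90, 180, 270):
            rot = self.holes @ _rotation_matrix(deg).T
            dd = np.linalg.norm(rot[:, None] - self.holes[None, :], axis=-1)
            if dd.min(axis=1).max() > atol:
                raise ValueError(f"hole set not invariant under {deg} deg rotation")


def generate_hole_layout(
    seed: int,
    holes_per_quadrant: int = DEFAULT_HOLES_PER_QUADRANT,
    min_spacing: float = DEFAULT_MIN_SPACING,
    wall_margin: float = DEFAULT_WALL_MARGIN,
    radius: float = DEFAULT_RADIUS,
    max_attempts_per_hole: int = 20000,
) -> ArenaLayout:
    """Rejection-sample a rotationally symmetric hole layout.

    Quadrant-1 holes are drawn uniformly in their sector (inside
    ``radius - wall_margin``); quadrants 2-4 are their exact 90/180/270
    degree rotations.  Every candidate is checked against the full orbit of
    all accepted holes (and its own rotational images), so the complete set
    satisfies ``min_spacing``.

    Raises :class:`PackingInfeasibleError` when the attempt budget runs out.
    """
    if holes_per_quadrant < 1:
        raise ValueError("holes_per_quadrant must be >= 1")
    if min_spacing <= 0:
        raise ValueError("min_spacing must be positive")
    rng = np.random.default_rng(seed)
    rmax = radius - wall_margin
    rots = [_rotation_matrix(d) for d in (0, 90, 180, 270)]
    accepted: list[np.ndarray] = []  # full orbit of accepted points
    q1: list[np.ndarray] = []
    attempts = 0
    budget = max_attempts_per_hole * holes_per_quadrant
    while len(q1) < holes_per_quadrant:
        if attempts > budget:
            raise PackingInfeasibleError(
                f"placed {len(q1)}/{holes_per_quadrant} quadrant-1 holes "
                f"after {attempts} attempts (min_spacing={min_spacing})"
            )
        attempts += 1
        # uniform over the quadrant-1 sector: angle in [45, 135), area-uniform radius
        ang = np.deg2rad(rng.uniform(45.0, 135.0))
        rr = rmax * np.sqrt(rng.uniform())
        cand = np.array([rr * np.cos(ang), rr * np.sin(ang)])
        orbit = np.stack([R @ cand for R in rots])
        # candidate orbit must respect spacing internally and to accepted holes
        dint = np.linalg.norm(orbit[:, None] - orbit[None, :], axis=-1)
        np.fill_diagonal(dint, np.inf)
        if dint.min() < min_spacing:
            continue
        if accepted:
            acc = np.concatenate(accepted)
            if np.linalg.norm(orbit[:, None] - acc[None, :], axis=-1).min() < min_spacing:
                continue
        q1.append(cand)
        accepted.append(orbit)

    holes = np.concatenate([np.stack([orb[k] for orb in accepted]) for k in range(4)])
    ids = np.arange(len(holes))
    layout = ArenaLayout(
        radius=radius,
        holes=holes,
        hole_ids=ids,
        min_spacing=min_spacing,
        wall_margin=wall_margin,
    )
    layout.validate()
    return layout


def rel_of(point, rotation_deg: float, center=(0.0, 0.0)) -> np.ndarray:
    """Rotationally equivalent location: rotate ``point`` CCW about the center.

    ``rotation_deg`` must be a multiple of 90 degrees.
    """
    if rotation_deg % 90 != 0:
        raise InvalidRotationError(f"rotation {rotation_deg} is not a multiple of 90")
    p = np.asarray(point, dtype=float) - np.asarray(center, dtype=float)
    k = int(rotation_deg // 90) % 4
    # exact quarter-turns avoid trig round-off
    for _ in range(k):
        p = np.array([-p[1], p[0]])
    return p + np.asarray(center, dtype=float)


def align_rotation_deg(entrance_quadrant: int) -> float:
    """CCW rotation bringing entrance ``entrance_quadrant`` onto the aligned start."""
    if entrance_quadrant not in (1, 2, 3, 4):
        raise ValueError(f"unknown entrance quadrant {entrance_quadrant}")
    return (entrance_quadrant - 1) * 90.0


def align_trajectory(traj, entrance_quadrant: int):
    """Rotate a trajectory into the common frame (start at top).

    Returns a new trajectory whose metadata records the applied rotation.
    """
    deg = align_rotation_deg(entrance_quadrant)
    k = int(deg // 90) % 4
    x, y = traj.x.copy(), traj.y.copy()
    for _ in range(k):
        x, y = -y, x
    meta = replace(traj.metadata, rotation_applied_deg=deg)
    return type(traj)(t=traj.t.copy(), x=x, y=y, metadata=meta)


def nearest_hole(layout: ArenaLayout, point) -> tuple[int, float]:
    """Hole id and distance of the hole nearest ``point`` (ties: lowest id)."""
    p = np.asarray(point, dtype=float)
    if np.hypot(p[0], p[1]) > layout.radius:
        raise OutOfArenaError(f"point {tuple(p)} outside arena disc")
    d = np.linalg.norm(layout.holes - p, axis=1)
    i = int(np.argmin(d))  # argmin returns first index, ids are ascending
    return int(layout.hole_ids[i]), float(d[i])


def select_target(
    layout: ArenaLayout,
    protocol: str,
    start_points,
    bisector_half_width: float = 10.0,
    axial_half_width: float = 6.0,
) -> int:
    """Pick the food hole under the protocol's placement constraints.

    static: wall distance > 35 cm and > 60 cm from the (single) start.
    random: wall distance > 30 cm and > 40 cm from every entrance.
    Both exclude holes within ``bisector_half_width`` of the line through
    the center perpendicular to each start-to-center line (avoids layouts
    reducible to a left/right choice).  Ties break to the lowest hole id.
    """
    starts = np.atleast_2d(np.asarray(start_points, dtype=float))
    if protocol == "static":
        min_wall, min_start = 35.0, 60.0
    elif protocol == "random":
        min_wall, min_start = 30.0, 40.0
    else:
        raise ValueError(f"unknown protocol {protocol!r}")

    wall_d = layout.radius - np.linalg.norm(layout.holes, axis=1)
    ok_wall = wall_d > min_wall
    start_d = np.linalg.norm(layout.holes[:, None] - starts[None, :], axis=-1)
    ok_start = start_d.min(axis=1) > min_start
    # exclude bands around the line through the center perpendicular to each
    # start-center line, and around the start-center axis itself: targets on
    # either line make the task degenerate (pure left/right choice, or a
    # direction indistinguishable from its rotational equivalent)
    ok_bis = np.ones(layout.n_holes, dtype=bool)
    for s in starts:
        u = s / np.linalg.norm(s)  # start direction; perpendicular line = {p : p.u = 0}
        ok_bis &= np.abs(layout.holes @ u) > bisector_half_width
        ok_bis &= np.abs(layout.holes @ np.array([-u[1], u[0]])) > axial_half_width
    ok = ok_wall & ok_start & ok_bis
    if not ok.any():
        for mask, name in ((ok_wall, "wall-distance"), (ok_start, "start-distance"), (ok_bis, "bisector-band")):
            if not mask.any():
                raise NoQualifyingHoleError(f"no hole satisfies the {name} constraint")
        raise NoQualifyingHoleError("no hole satisfies the joint placement constraints")
    return int(layout.hole_ids[np.flatnonzero(ok)[0]])


def write_layout(layout: ArenaLayout, path) -> None:
    """Write the layout as plain tabular text (hole_id, x_cm, y_cm)."""
    df = pd.DataFrame(
        {"hole_id": layout.hole_ids, "x_cm": layout.holes[:, 0], "y_cm": layout.holes[:, 1]}
    )
    df.to_csv(path, index=False)


def read_layout(path, radius: float = DEFAULT_RADIUS, **kwargs) -> ArenaLayout:
    """Read a layout file written by :func:`write_layout`."""
    df = pd.read_csv(path)
    required = {"hole_id", "x_cm", "y_cm"}
    if not required.issubset(df.columns):
        raise ValueError(f"layout file must have columns {sorted(required)}")
    df = df.sort_values("hole_id")
    return ArenaLayout(
        radius=radius,
        holes=df[["x_cm", "y_cm"]].to_numpy(dtype=float),
        hole_ids=df["hole_id"].to_numpy(dtype=int),
        **kwargs,
    )
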