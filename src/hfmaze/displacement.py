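"""Lattice displacement maps: preferred stepping direction per arena site.

The arena's bounding square is covered by an L x L lattice (default
L = 11, a few centimeters per box).  Trajectories become sequences of
visited sites; transitions between 4-adjacent sites are counted per site
and direction, pooled over mice.  Observed counts are blended with a null
stepping probability P0 = 1/4 through the union rule

    W_dir(x, y) = S_dir/ns + P0 - (S_dir/ns) * P0,

normalized by W_out = sum of the four direction weights, giving stepping
probabilities P_dir = W_dir / W_out and the displacement vector

    M(x, y) = (P_right - P_left, P_up - P_down).

Sites with no data fall back to P_dir = P0 and M = 0.  ``ns`` in the
weight rule is the total number of steps out of the site being updated
(the three-step worked configuration fixes this normalization).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import linregress

DEFAULT_L = 11
P0 = 0.25

# direction order used throughout: right, left, up, down
DIRECTIONS = ("right", "left", "up", "down")
_DIR_STEP = {(1, 0): 0, (-1, 0): 1, (0, 1): 2, (0, -1): 3}


@dataclass(frozen=True)
class LatticeSpec:
    """L x L lattice over the square [-half_extent, +half_extent]^2."""

    L: int = DEFAULT_L
    half_extent: float = 60.0

    def __post_init__(self):
        if self.L < 2:
            raise ValueError("lattice dimension L must be >= 2")

    @property
    def box_size(self) -> float:
        return 2 * self.half_extent / self.L

    def site_of(self, x, y) -> np.ndarray:
        """Map arena coordinates to integer lattice sites in {1..L}^2."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        if np.any(np.abs(x) > self.half_extent) or np.any(np.abs(y) > self.half_extent):
            raise ValueError("point outside lattice bounding square")
        ix = np.clip(np.floor((x + self.half_extent) / self.box_size).astype(int), 0, self.L - 1)
        iy = np.clip(np.floor((y + self.half_extent) / self.box_size).astype(int), 0, self.L - 1)
        return np.stack([ix + 1, iy + 1], axis=-1)

    def site_center(self, sx, sy) -> np.ndarray:
        """Arena coordinates of the center of site (sx, sy), 1-based."""
        cx = (np.asarray(sx) - 0.5) * self.box_size - self.half_extent
        cy = (np.asarray(sy) - 0.5) * self.box_size - self.half_extent
        return np.stack([cx, cy], axis=-1)


def rasterize(traj, lattice: LatticeSpec, decompose_diagonals: bool = True) -> np.ndarray:
    """Sequence of visited lattice sites, consecutive duplicates collapsed.

    Samples where the animal stays in the same box are ignored (no
    self-steps).  A transition between sites that are not 4-adjacent (fast
    movement can skip boxes between frames) is decomposed into an
    axis-aligned staircase taking all horizontal steps first; with
    ``decompose_diagonals=False`` such transitions are dropped instead.

    Returns an (n, 2) int array of 1-based (x, y) sites.
    """
    sites = lattice.site_of(traj.x, traj.y)
    if len(sites) == 0:
        return sites.reshape(0, 2)
    keep = np.ones(len(sites), dtype=bool)
    keep[1:] = np.any(np.diff(sites, axis=0) != 0, axis=1)
    sites = sites[keep]
    out = [sites[0]]
    for nxt in sites[1:]:
        cur = out[-1]
        dx, dy = int(nxt[0] - cur[0]), int(nxt[1] - cur[1])
        if abs(dx) + abs(dy) == 1:
            out.append(nxt)
        elif decompose_diagonals:
            x, y = int(cur[0]), int(cur[1])
            for _ in range(abs(dx)):  # horizontal staircase leg first
                x += int(np.sign(dx))
                out.append(np.array([x, y]))
            for _ in range(abs(dy)):
                y += int(np.sign(dy))
                out.append(np.array([x, y]))
        else:
            out.append(nxt)  # counted as sequence break, not a step
    return np.asarray(out, dtype=int)


@dataclass(frozen=True)
class StepCounts:
    """Per-site directional step counts S and the trial total ns."""

    L: int
    S: np.ndarray  # (L, L, 4) int, indexed [x-1, y-1, direction]
    ns: int

    def __post_init__(self):
        if np.any(self.S < 0):
            raise ValueError("negative step counts")


def count_steps(site_sequences, L: int = DEFAULT_L) -> StepCounts:
    """Pool 4-adjacent transitions over all sequences (all mice, one trial)."""
    S = np.zeros((L, L, 4), dtype=int)
    for seq in site_sequences:
        seq = np.asarray(seq, dtype=int)
        for (x, y), (nx, ny) in zip(seq[:-1], seq[1:]):
            d = _DIR_STEP.get((int(nx - x), int(ny - y)))
            if d is not None:  # non-adjacent pairs are sequence breaks
                S[x - 1, y - 1, d] += 1
    return StepCounts(L=L, S=S, ns=int(S.sum()))


@dataclass(frozen=True)
class DisplacementField:
    """Weights, stepping probabilities and displacement vectors on the lattice."""

    L: int
    W: np.ndarray     # (L, L, 4)
    Wout: np.ndarray  # (L, L)
    P: np.ndarray     # (L, L, 4)
    M: np.ndarray     # (L, L, 2): (Mh, Mv)
    ns: int
    counts: StepCounts | None = None

    @property
    def Mh(self) -> np.ndarray:
        return self.M[..., 0]

    @property
    def Mv(self) -> np.ndarray:
        return self.M[..., 1]

    def total_vector(self) -> np.ndarray:
        """Sum of M over all lattice sites (the TEV direction source)."""
        return self.M.sum(axis=(0, 1))

    def to_frame(self) -> pd.DataFrame:
        L = self.L
        xs, ys = np.meshgrid(np.arange(1, L + 1), np.arange(1, L + 1), indexing="ij")
        ns_site = self.counts.S.sum(axis=-1) if self.counts is not None else np.zeros((L, L), int)
        return pd.DataFrame(
            {
                "x": xs.ravel(),
                "y": ys.ravel(),
                "Mh": self.M[..., 0].ravel(),
                "Mv": self.M[..., 1].ravel(),
                "ns_site": ns_site.ravel(),
                "null_site": (ns_site.ravel() == 0),
            }
        )


def field_from_counts(counts: StepCounts, p0: float = P0) -> DisplacementField:
    """Apply the weight/normalization equations to observed step counts.

    The observed stepping fraction at a site is S_dir / ns with ns the
    total steps out of that site (the worked three-step example and the
    reported fallback magnitudes pin the normalization to the per-site
    total, not the trial-wide one).  A trial with no steps at all returns
    the all-null field (every P = p0, M = 0).
    """
    S = counts.S.astype(float)
    ns_site = S.sum(axis=-1, keepdims=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(ns_site > 0, S / np.where(ns_site > 0, ns_site, 1.0), 0.0)
    W = frac + p0 - frac * p0
    Wout = W.sum(axis=-1)
    P = W / Wout[..., None]
    M = np.stack([P[..., 0] - P[..., 1], P[..., 2] - P[..., 3]], axis=-1)
    return DisplacementField(L=counts.L, W=W, Wout=Wout, P=P, M=M, ns=counts.ns, counts=counts)


def displacement_field(trajectories, lattice: LatticeSpec | None = None) -> DisplacementField:
    """Convenience: rasterize trajectories (one per mouse), count, and weight."""
    lattice = lattice or LatticeSpec()
    seqs = [rasterize(tr, lattice) for tr in trajectories]
    return field_from_counts(count_steps(seqs, L=lattice.L))


def box_scaling(traj, L_values, half_extent: float = 60.0):
    """Occupied-box count versus lattice dimension L, with a linear fit.

    A trajectory of dimension 1 (any simple curve) gives counts growing
    linearly in L.  Returns (counts, slope, r_squared).
    """
    L_values = list(L_values)
    if len(L_values) < 3:
        raise ValueError("need at least 3 lattice dimensions")
    counts = []
    for L in L_values:
        lat = LatticeSpec(L=L, half_extent=half_extent)
        sites = lat.site_of(traj.x, traj.y)
        counts.append(len(np.unique(sites, axis=0)))
    counts = np.asarray(counts, dtype=float)
    if np.ptp(counts) == 0:
        return counts, 0.0, 1.0
    fit = linregress(np.asarray(L_values, dtype=float), counts)
    return counts, float(fit.slope), float(fit.rvalue**2)
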