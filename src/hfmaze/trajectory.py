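"""Trajectory container, file I/O and speed estimation.

Trajectories are nose-point paths sampled nominally at 30 Hz, stored as
plain comma-separated text with a ``time_s, x_cm, y_cm`` header.  A
manifest table (one row per trial) carries the metadata that the trajectory
files themselves do not.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import uniform_filter1d

from .errors import GapTooLongError, TrajectoryFormatError

SAMPLE_RATE = 30.0
DEFAULT_MAX_GAP = 0.5  # s
DEFAULT_SMOOTHING_WINDOW = 5  # samples


@dataclass(frozen=True)
class TrialMeta:
    mouse_id: str = ""
    trial_index: int = 0
    entrance_quadrant: int = 1
    protocol_stage: str = ""
    target_hole_id: int = -1
    probe_flag: bool = False
    rotation_applied_deg: float = 0.0
    n_clipped: int = 0


@dataclass(frozen=True)
class Trajectory:
    """Uniformly sampled nose-point path with trial metadata."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    metadata: TrialMeta = field(default_factory=TrialMeta)

    def __post_init__(self):
        t, x, y = (np.asarray(a, dtype=float) for a in (self.t, self.x, self.y))
        if not (len(t) == len(x) == len(y)):
            raise TrajectoryFormatError("t, x, y must have equal lengths")
        if len(t) > 1 and not np.all(np.diff(t) > 0):
            raise TrajectoryFormatError("time must be strictly increasing")
        object.__setattr__(self, "t", t)
        object.__setattr__(self, "x", x)
        object.__setattr__(self, "y", y)

    def __len__(self) -> int:
        return len(self.t)

    @property
    def xy(self) -> np.ndarray:
        return np.column_stack([self.x, self.y])

    @property
    def duration(self) -> float:
        return float(self.t[-1] - self.t[0]) if len(self) else 0.0

    def path_length(self) -> float:
        """Total traveled distance (cm)."""
        return float(np.sum(np.hypot(np.diff(self.x), np.diff(self.y))))

    def cumulative_length(self) -> np.ndarray:
        steps = np.hypot(np.diff(self.x), np.diff(self.y))
        return np.concatenate([[0.0], np.cumsum(steps)])

    def slice(self, i: int, j: int) -> "Trajectory":
        return Trajectory(self.t[i:j], self.x[i:j], self.y[i:j], self.metadata)


def write_trajectory(traj: Trajectory, path) -> None:
    pd.DataFrame({"time_s": traj.t, "x_cm": traj.x, "y_cm": traj.y}).to_csv(path, index=False)


def read_trajectory(
    path,
    layout=None,
    metadata: TrialMeta | None = None,
    max_gap: float = DEFAULT_MAX_GAP,
) -> Trajectory:
    """Read, validate and regularize a trajectory file.

    Missing samples spanning at most ``max_gap`` seconds are filled by
    linear interpolation on the nominal time base; longer gaps raise
    :class:`GapTooLongError`.  When a layout is given, points outside the
    arena disc (beyond a 1 cm tolerance) are clipped radially onto it and
    counted in ``metadata.n_clipped``.
    """
    df = pd.read_csv(path)
    required = ["time_s", "x_cm", "y_cm"]
    if not all(c in df.columns for c in required):
        raise TrajectoryFormatError(
            f"trajectory file {path} must have header columns {required}"
        )
    t = df["time_s"].to_numpy(dtype=float)
    x = df["x_cm"].to_numpy(dtype=float)
    y = df["y_cm"].to_numpy(dtype=float)
    if len(t) == 0:
        raise TrajectoryFormatError(f"empty trajectory file {path}")
    if len(t) > 1:
        dt = np.diff(t)
        if np.any(dt <= 0):
            raise TrajectoryFormatError(f"non-monotone time column in {path}")
        nominal = float(np.median(dt))
        if np.any(dt > max_gap + nominal / 2):
            i = int(np.argmax(dt))
            raise GapTooLongError(
                f"gap of {dt.max():.3f} s at t={t[i]:.3f} exceeds max_gap={max_gap}"
            )
        if np.any(dt > 1.5 * nominal):
            n_steps = int(round((t[-1] - t[0]) / nominal))
            tt = t[0] + nominal * np.arange(n_steps + 1)
            x = np.interp(tt, t, x)
            y = np.interp(tt, t, y)
            t = tt
    n_clipped = 0
    if layout is not None:
        r = np.hypot(x, y)
        out = r > layout.radius + 1.0
        n_clipped = int(out.sum())
        far = r > layout.radius
        if far.any():
            scale = layout.radius / r[far]
            x = x.copy()
            y = y.copy()
            x[far] *= scale
            y[far] *= scale
    meta = metadata or TrialMeta()
    meta = replace(meta, n_clipped=n_clipped)
    return Trajectory(t=t, x=x, y=y, metadata=meta)


def instantaneous_speed(
    traj: Trajectory, smoothing_window: int = DEFAULT_SMOOTHING_WINDOW
) -> np.ndarray:
    """Centered finite-difference speed (cm/s), boxcar smoothed.

    The returned series has the same length as the trajectory; endpoints
    use one-sided differences.
    """
    n = len(traj)
    if n < 2:
        raise ValueError("speed needs at least 2 samples")
    vx = np.gradient(traj.x, traj.t)
    vy = np.gradient(traj.y, traj.t)
    speed = np.hypot(vx, vy)
    if smoothing_window and smoothing_window > 1:
        speed = uniform_filter1d(speed, size=int(smoothing_window), mode="nearest")
    return speed


# --- manifest -----------------------------------------------------------

MANIFEST_COLUMNS = [
    "file",
    "mouse_id",
    "trial_index",
    "entrance_quadrant",
    "protocol_stage",
    "target_hole_id",
    "probe_flag",
]


def write_manifest(rows: list[dict], path) -> None:
    pd.DataFrame(rows, columns=MANIFEST_COLUMNS).to_csv(path, index=False)


def read_manifest(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(MANIFEST_COLUMNS) - set(df.columns)
    if missing:
        raise TrajectoryFormatError(f"manifest missing columns {sorted(missing)}")
    return df


def meta_from_row(row) -> TrialMeta:
    return TrialMeta(
        mouse_id=str(row["mouse_id"]),
        trial_index=int(row["trial_index"]),
        entrance_quadrant=int(row["entrance_quadrant"]),
        protocol_stage=str(row["protocol_stage"]),
        target_hole_id=int(row["target_hole_id"]),
        probe_flag=bool(row["probe_flag"]),
    )
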