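"""Per-trial scalar metrics and the exponential learning-curve fit.

The headline trial metrics are the latency to reach the target hole, the
total traveled distance d_total, and the normalized trajectory length
d_total / d_target (1 is optimal, a straight run from start to food).
Learning speed is summarized by fitting d_total = B * exp(-Trial / K):
K is the characteristic learning timescale in trial units and its relative
uncertainty CV = sd(K) / K flags whether the decay is real (CV << 1) or
the data are effectively flat (CV > 1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import DegenerateGeometryError
from .trajectory import Trajectory, instantaneous_speed


@dataclass(frozen=True)
class Latency:
    time_s: float
    censored: bool  # True when the target was never reached (time = duration)


@dataclass(frozen=True)
class TrialMetrics:
    latency_s: float
    censored: bool
    d_total_cm: float
    d_target_cm: float
    normalized_length: float
    mean_speed_cm_s: float
    mean_heading_deviation_deg: float
    mean_distance_to_food_line_cm: float


@dataclass(frozen=True)
class LearningFit:
    B: float
    K: float
    K_sd: float
    CV: float
    unstable: bool  # CV > 1: the decay timescale is not identifiable


def latency_to_target(traj: Trajectory, target_xy, capture_radius: float) -> Latency:
    """Time from the first sample to the first entry within ``capture_radius``.

    Returns a censored latency equal to the trial duration when the nose
    never comes within the capture radius.
    """
    if len(traj) == 0:
        raise ValueError("empty trajectory")
    target_xy = np.asarray(target_xy, dtype=float)
    d = np.hypot(traj.x - target_xy[0], traj.y - target_xy[1])
    hit = np.flatnonzero(d <= capture_radius)
    if hit.size == 0:
        return Latency(time_s=traj.duration, censored=True)
    return Latency(time_s=float(traj.t[hit[0]] - traj.t[0]), censored=False)


def truncate_at_capture(traj: Trajectory, target_xy, capture_radius: float) -> Trajectory:
    """Trajectory up to (and including) the first target capture sample."""
    target_xy = np.asarray(target_xy, dtype=float)
    d = np.hypot(traj.x - target_xy[0], traj.y - target_xy[1])
    hit = np.flatnonzero(d <= capture_radius)
    if hit.size == 0:
        return traj
    return traj.slice(0, int(hit[0]) + 1)


def normalized_length(traj: Trajectory, start, target) -> float:
    """Total path length over the straight start-to-target distance.

    The caller is responsible for truncating the path at first capture
    (see :func:`truncate_at_capture`); a straight run scores exactly 1.
    """
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    d_target = float(np.linalg.norm(target - start))
    if d_target == 0.0:
        raise DegenerateGeometryError("start coincides with target")
    return traj.path_length() / d_target


def _segment_distance(points: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(points - a, axis=1)
    tt = np.clip((points - a) @ ab / denom, 0.0, 1.0)
    proj = a + tt[:, None] * ab
    return np.linalg.norm(points - proj, axis=1)


def heading_and_line_deviation(traj: Trajectory, start, target):
    """Per-sample heading deviation (deg) and distance to the food line (cm).

    Heading deviation is the angle in [0, 180] between the instantaneous
    displacement and the direction from the current point to the target
    (the reference direction is re-evaluated at every sample, since the
    bearing to the food changes as the animal moves).  The food line is the
    straight start-to-target segment.  Zero-length displacement samples are
    skipped in the heading series.
    """
    start = np.asarray(start, dtype=float)
    target = np.asarray(target, dtype=float)
    p = traj.xy
    disp = np.diff(p, axis=0)
    to_target = target - p[:-1]
    norm_d = np.linalg.norm(disp, axis=1)
    norm_t = np.linalg.norm(to_target, axis=1)
    moving = (norm_d > 0) & (norm_t > 0)
    cosang = np.einsum("ij,ij->i", disp[moving], to_target[moving]) / (
        norm_d[moving] * norm_t[moving]
    )
    heading_deg = np.rad2deg(np.arccos(np.clip(cosang, -1.0, 1.0)))
    line_cm = _segment_distance(p, start, target)
    return heading_deg, line_cm


def fit_learning_curve(d_total, trials=None) -> LearningFit:
    """Nonlinear least squares of d_total = B * exp(-Trial / K).

    ``K_sd`` comes from the fit's parameter covariance; non-decaying data
    yield ``unstable=True`` (CV > 1) rather than an exception, since a flat
    series is a legitimate experimental outcome (no distance learning).
    """
    y = np.asarray(d_total, dtype=float)
    if trials is None:
        trials = np.arange(1, len(y) + 1, dtype=float)
    else:
        trials = np.asarray(trials, dtype=float)
    if len(y) < 4:
        raise ValueError("learning fit needs at least 4 trials")

    def model(t, B, K):
        return B * np.exp(-t / K)

    # log-linear init; flat or rising data get a long initial timescale
    with np.errstate(divide="ignore", invalid="ignore"):
        logy = np.log(np.maximum(y, 1e-12))
    slope = np.polyfit(trials, logy, 1)[0]
    K0 = -1.0 / slope if slope < -1e-9 else 10.0 * (trials[-1] - trials[0] + 1)
    B0 = float(np.exp(logy[0] + trials[0] / K0))
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            popt, pcov = curve_fit(
                model,
                trials,
                y,
                p0=[B0, K0],
                bounds=([0.0, 1e-6], [np.inf, np.inf]),
                maxfev=20000,
            )
        B, K = popt
        K_sd = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else np.inf
    except (RuntimeError, ValueError):
        B, K, K_sd = float(y.mean()), np.inf, np.inf
    CV = K_sd / K if np.isfinite(K) and K > 0 else np.inf
    if not np.isfinite(CV):
        CV = np.inf
    # a timescale far beyond the observation window is not identifiable
    # (flat or rising data): flag it rather than trusting the tiny formal
    # covariance of a degenerate fit
    span = float(trials[-1] - trials[0]) or 1.0
    if K > 10.0 * span:
        CV = np.inf
    return LearningFit(B=float(B), K=float(K), K_sd=float(K_sd), CV=float(CV), unstable=bool(CV > 1))


def compute_trial_metrics(
    traj: Trajectory, start, target_xy, capture_radius: float
) -> TrialMetrics:
    """All scalar metrics for one trial (path truncated at first capture)."""
    lat = latency_to_target(traj, target_xy, capture_radius)
    part = truncate_at_capture(traj, target_xy, capture_radius)
    d_total = part.path_length()
    d_target = float(np.linalg.norm(np.asarray(target_xy, float) - np.asarray(start, float)))
    heading, line = heading_and_line_deviation(part, start, target_xy)
    speed = instantaneous_speed(part) if len(part) >= 2 else np.array([0.0])
    return TrialMetrics(
        latency_s=lat.time_s,
        censored=lat.censored,
        d_total_cm=d_total,
        d_target_cm=d_target,
        normalized_length=d_total / d_target if d_target > 0 else np.nan,
        mean_speed_cm_s=float(speed.mean()),
        mean_heading_deviation_deg=float(heading.mean()) if heading.size else np.nan,
        mean_distance_to_food_line_cm=float(line.mean()),
    )
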