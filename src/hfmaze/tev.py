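"""Jackknife directionality inference and the Target Estimation Vector.

For a trial with N mice, leave-one-out resampling yields N displacement
fields M_k.  Summing each field over all lattice sites gives a vector u_k
whose direction estimates the learned heading.  Directionality strength is
the angular standard deviation of the u_k about their mean direction,

    sigma = sqrt( 1/(N-1) * sum_k theta_k^2 ),  theta_k in (-180, 180],

and its significance is the probability that N independent uniform angles
produce an angular S.D. at or below the observed one (small p = strong
directionality).  The null density rho(sigma) is estimated by Monte Carlo;
below Monte-Carlo resolution an analytic ball-volume tail takes over.

The TEV combines direction (from the fields) with magnitude D, the
distance from the trial origin (start, or target B in the B-to-A probe) to
the mean of the hole checks within 20 cm of the target.  When no preferred
direction is detected the summed field vector u_k itself is the TEV.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.special import gammaln

from .displacement import DisplacementField, StepCounts, count_steps, field_from_counts

DEFAULT_N_DRAWS = 10_000
DEFAULT_SD_THRESHOLD = 5.0  # deg; the display/significance cut (p < 1e-7 at N=8)


# --- angular statistics -------------------------------------------------


def wrap_deg(angles) -> np.ndarray:
    """Wrap angles in degrees to (-180, 180]."""
    a = np.asarray(angles, dtype=float)
    return -((-a + 180.0) % 360.0 - 180.0)


def angular_sd(vectors) -> float:
    """Angular standard deviation (deg) of 2-D vectors about their mean direction.

    The sample is rotated so the mean (resultant) direction is 0 degrees,
    angles are wrapped to (-180, 180], and sigma = sqrt(sum theta^2 / (N-1)).
    Zero vectors are excluded with a warning; an all-zero sample is
    undefined (NaN).
    """
    v = np.atleast_2d(np.asarray(vectors, dtype=float))
    norms = np.linalg.norm(v, axis=1)
    nz = norms > 0
    if not nz.all():
        warnings.warn(f"excluding {int((~nz).sum())} zero vector(s) from angular S.D.")
    v = v[nz]
    if len(v) == 0:
        return float("nan")
    if len(v) < 2:
        raise ValueError("angular S.D. needs at least 2 non-zero vectors")
    ang = np.rad2deg(np.arctan2(v[:, 1], v[:, 0]))
    mean_dir = np.rad2deg(np.arctan2(np.sin(np.deg2rad(ang)).mean(), np.cos(np.deg2rad(ang)).mean()))
    theta = wrap_deg(ang - mean_dir)
    return float(np.sqrt(np.sum(theta**2) / (len(v) - 1)))


def _sd_of_angles(theta: np.ndarray) -> np.ndarray:
    """sigma = sqrt(1/(N-1) sum theta^2) along the last axis."""
    n = theta.shape[-1]
    return np.sqrt(np.sum(theta**2, axis=-1) / (n - 1))


def _log_ball_volume(n: int, log_r: float) -> float:
    """log volume of the n-ball of radius exp(log_r)."""
    return n / 2 * np.log(np.pi) - gammaln(n / 2 + 1) + n * log_r


@dataclass(frozen=True)
class AngularNull:
    """Empirical null of the angular S.D. of N uniform angles."""

    N: int
    n_draws: int
    sigmas: np.ndarray  # sorted
    centered: bool
    seed: int

    @property
    def sigma_max(self) -> float:
        return float(self.sigmas[-1])


def build_null(
    N: int,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
    centered: bool = False,
) -> AngularNull:
    """Monte-Carlo null: S.D. of N uniform angles on (-180, 180], repeated.

    ``centered=False`` (default) applies the zero-mean S.D. formula to the
    raw draws; ``centered=True`` first rotates each draw so its circular
    mean is zero, matching how observed samples are treated.  The two
    constructions bracket the reference tail behavior.
    """
    if N < 2:
        raise ValueError("null needs N >= 2 angles")
    if n_draws < 1000:
        raise ValueError("need at least 1000 draws for a usable null")
    rng = np.random.default_rng(seed)
    theta = rng.uniform(-180.0, 180.0, size=(n_draws, N))
    if centered:
        mean_dir = np.rad2deg(
            np.arctan2(
                np.sin(np.deg2rad(theta)).mean(axis=1),
                np.cos(np.deg2rad(theta)).mean(axis=1),
            )
        )
        theta = wrap_deg(theta - mean_dir[:, None])
    sig = np.sort(_sd_of_angles(theta))
    return AngularNull(N=N, n_draws=n_draws, sigmas=sig, centered=centered, seed=seed)


@dataclass(frozen=True)
class PValue:
    p: float
    source: str  # "mc" (empirical CDF) or "tail" (analytic ball volume)

    def __float__(self) -> float:
        return self.p


def analytic_tail_p(N: int, sd: float, centered: bool = False) -> float:
    """Small-sigma tail of the null, from the volume of the sphere
    sum theta_k^2 <= (N-1) sd^2 relative to the uniform angle hypercube.

    Uncentered: p = V_N(r) / 360^N with r = sqrt(N-1) * sd.
    Centered: the sample lies in the (N-1)-dim complement of the common
    rotation, giving p = sqrt(N) * V_{N-1}(r) / 360^(N-1).
    Valid for r <= 180 (ball inside the hypercube).
    """
    r = np.sqrt(N - 1) * sd
    if sd == 0:
        return 0.0
    if r > 180.0:
        raise ValueError("analytic tail only valid for sqrt(N-1)*sd <= 180")
    if centered:
        logp = 0.5 * np.log(N) + _log_ball_volume(N - 1, np.log(r)) - (N - 1) * np.log(360.0)
    else:
        logp = _log_ball_volume(N, np.log(r)) - N * np.log(360.0)
    return float(np.exp(logp))


def p_value(null: AngularNull, sd: float, tail_factor: float = 10.0) -> PValue:
    """P(sigma <= sd) under the uniform-angle null.

    Uses the empirical CDF of the Monte-Carlo draws; when that estimate
    falls below ``tail_factor / n_draws`` (too few draws to resolve it),
    the analytic ball-volume tail is reported instead, with the source
    flagged.
    """
    if sd < 0:
        raise ValueError("S.D. must be non-negative")
    if sd == 0:
        return PValue(0.0, "mc")
    k = int(np.searchsorted(null.sigmas, sd, side="right"))
    p_mc = k / null.n_draws
    if p_mc < tail_factor / null.n_draws and np.sqrt(null.N - 1) * sd <= 180.0:
        return PValue(analytic_tail_p(null.N, sd, centered=null.centered), "tail")
    return PValue(p_mc, "mc")


# --- jackknife ----------------------------------------------------------


@dataclass(frozen=True)
class JackknifeEnsemble:
    """N leave-one-out displacement fields and their per-site vector mean."""

    N: int
    fields: list
    mean_M: np.ndarray  # (L, L, 2)

    def u_vectors(self) -> np.ndarray:
        """(N, 2) summed-field vectors u_k, one per jackknife sample."""
        return np.stack([f.total_vector() for f in self.fields])

    def site_angular_sd(self) -> np.ndarray:
        """(L, L) angular S.D. of the per-site vectors across samples."""
        L = self.fields[0].L
        out = np.full((L, L), np.nan)
        M = np.stack([f.M for f in self.fields])  # (N, L, L, 2)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for i in range(L):
                for j in range(L):
                    v = M[:, i, j, :]
                    if np.all(np.linalg.norm(v, axis=1) > 0):
                        out[i, j] = angular_sd(v)
        return out


def jackknife_fields(site_sequences_by_mouse, L: int) -> JackknifeEnsemble:
    """Leave-one-out displacement fields over a cohort of N mice.

    ``site_sequences_by_mouse`` holds, per mouse, the rasterized site
    sequence(s) of that mouse's trajectory in the trial.
    """
    N = len(site_sequences_by_mouse)
    if N < 3:
        raise ValueError(f"jackknife needs at least 3 mice, got {N}")
    fields = []
    for k in range(N):
        pooled = []
        for m, seqs in enumerate(site_sequences_by_mouse):
            if m == k:
                continue
            if isinstance(seqs, np.ndarray) and seqs.ndim == 2:
                pooled.append(seqs)
            else:
                pooled.extend(seqs)
        fields.append(field_from_counts(count_steps(pooled, L=L)))
    mean_M = np.mean([f.M for f in fields], axis=0)
    return JackknifeEnsemble(N=N, fields=fields, mean_M=mean_M)


# --- target estimation vector ------------------------------------------


@dataclass(frozen=True)
class TEVResult:
    direction: np.ndarray       # unit vector
    magnitude: float            # cm (significant branch) or |mean u_k|
    D_vec: np.ndarray           # jackknife-averaged TEV
    sigma_D: float              # cm, sqrt(lambda1 + lambda2) of restricted checks
    angular_sd_deg: float
    p_directionality: float
    p_source: str
    deviation_deg: float        # angle between the TEV and origin->target
    branch: str                 # "significant" or "fallback"


def angle_between_deg(a, b) -> float:
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    na, nb = np.linalg.norm(a), np.linalg.norm(b)
    if na == 0 or nb == 0:
        return float("nan")
    return float(np.rad2deg(np.arccos(np.clip(a @ b / (na * nb), -1.0, 1.0))))


def compute_tev(
    ensemble: JackknifeEnsemble,
    check_stats,
    origin,
    target,
    sd_threshold: float = DEFAULT_SD_THRESHOLD,
    null: AngularNull | None = None,
    n_draws: int = DEFAULT_N_DRAWS,
    seed: int = 0,
    centered_null: bool = False,
) -> TEVResult:
    """Combine field directions and hole-check positions into the TEV.

    When the jackknife directions are tight (angular S.D. at or below
    ``sd_threshold``) the TEV magnitude is the distance from ``origin`` to
    the restricted hole-check mean; otherwise each sample's TEV is its raw
    summed field vector u_k (no preferred direction detected).
    """
    origin = np.asarray(origin, dtype=float)
    target = np.asarray(target, dtype=float)
    u = ensemble.u_vectors()
    sd = angular_sd(u)
    if null is None:
        null = build_null(ensemble.N, n_draws=n_draws, seed=seed, centered=centered_null)
    pv = p_value(null, sd) if np.isfinite(sd) else PValue(float("nan"), "mc")

    restricted_mean = getattr(check_stats, "restricted_mean", None)
    sigma_d = getattr(check_stats, "sigma_D", float("nan"))
    significant = np.isfinite(sd) and sd <= sd_threshold
    if significant and restricted_mean is None:
        warnings.warn(
            "significant directionality but no hole checks within the near "
            "radius of the target; falling back to summed-field magnitudes"
        )
        significant = False
    if significant:
        D = float(np.linalg.norm(np.asarray(restricted_mean) - origin))
        unit = u / np.linalg.norm(u, axis=1, keepdims=True)
        D_k = D * unit
        branch = "significant"
    else:
        D_k = u
        D = float(np.linalg.norm(u.mean(axis=0)))
        branch = "fallback"
    D_vec = D_k.mean(axis=0)
    nvec = np.linalg.norm(D_vec)
    direction = D_vec / nvec if nvec > 0 else np.array([np.nan, np.nan])
    deviation = angle_between_deg(D_vec, target - origin)
    return TEVResult(
        direction=direction,
        magnitude=D,
        D_vec=D_vec,
        sigma_D=float(sigma_d),
        angular_sd_deg=float(sd),
        p_directionality=pv.p,
        p_source=pv.source,
        deviation_deg=deviation,
        branch=branch,
    )
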