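"""Figure rendering: displacement-map arrows, hole-check maps, occupancy."""

from __future__ import annotations

import matplotlib

matplotlib.use("Agg")

import matplotlib.pyplot as plt
import numpy as np
from matplotlib.patches import Circle, Ellipse, Wedge

from .displacement import LatticeSpec


def _arena_axes(ax, radius):
    ax.add_patch(Circle((0, 0), radius, fill=False, lw=1.5, color="k"))
    ax.set_xlim(-radius * 1.05, radius * 1.05)
    ax.set_ylim(-radius * 1.05, radius * 1.05)
    ax.set_aspect("equal")
    ax.set_xlabel("x (cm)")
    ax.set_ylabel("y (cm)")


def plot_displacement_field(
    ensemble, layout, tev=None, target_xy=None, origin=None, sd_mask_deg=5.0, ax=None
):
    """Mean jackknife field as arrows (only tight-direction sites), with the
    TEV arrow and its angular-S.D. sector."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    _arena_axes(ax, layout.radius)
    lattice = LatticeSpec(L=ensemble.fields[0].L, half_extent=layout.radius)
    M = ensemble.mean_M
    sds = ensemble.site_angular_sd()
    mags = np.linalg.norm(M, axis=-1)
    show = np.isfinite(sds) & (sds <= sd_mask_deg) & (mags > 0)
    scale = 0.45 * lattice.box_size / max(mags.max(), 1e-12)
    cmap = plt.get_cmap("coolwarm")
    for i in range(lattice.L):
        for j in range(lattice.L):
            if not show[i, j]:
                continue
            cx, cy = lattice.site_center(i + 1, j + 1)
            ax.arrow(
                cx, cy, M[i, j, 0] * scale, M[i, j, 1] * scale,
                head_width=0.18 * lattice.box_size,
                color=cmap(min(mags[i, j] / mags.max(), 1.0)), lw=1,
            )
    if origin is None:
        origin = np.array([0.0, layout.radius])
    if tev is not None and np.all(np.isfinite(tev.D_vec)):
        ax.annotate(
            "", xy=origin + tev.D_vec, xytext=origin,
            arrowprops=dict(color="deeppink", width=2, headwidth=8),
        )
        ang = np.rad2deg(np.arctan2(tev.D_vec[1], tev.D_vec[0]))
        sd = tev.angular_sd_deg
        if np.isfinite(sd):
            ax.add_patch(
                Wedge(origin, np.linalg.norm(tev.D_vec), ang - sd, ang + sd,
                      color="pink", alpha=0.4)
            )
    if target_xy is not None:
        ax.annotate(
            "", xy=target_xy, xytext=origin,
            arrowprops=dict(color="purple", width=1.5, headwidth=7, alpha=0.7),
        )
        ax.plot(*target_xy, "o", color="red", ms=8, mfc="none")
    return ax


def plot_check_distribution(stats, layout, target_xy=None, ax=None):
    """Per-hole check frequencies as scaled circles with covariance ellipses."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    _arena_axes(ax, layout.radius)
    ax.plot(layout.holes[:, 0], layout.holes[:, 1], ".", color="0.8", ms=3)
    if stats.n_events:
        pmax = max(stats.P.values())
        for hid, p in stats.P.items():
            x, y = layout.hole_xy(hid)
            ax.plot(x, y, "o", color=plt.get_cmap("RdPu")(0.3 + 0.7 * p / pmax),
                    ms=4 + 14 * p / pmax, alpha=0.85)
        for mean, cov, color in (
            (stats.mean, stats.covariance, "k"),
            (stats.restricted_mean, stats.restricted_covariance, "green"),
        ):
            if mean is None or cov is None:
                continue
            vals, vecs = np.linalg.eigh(cov)
            ang = np.rad2deg(np.arctan2(vecs[1, -1], vecs[0, -1]))
            ax.add_patch(
                Ellipse(mean, 2 * np.sqrt(max(vals[-1], 0)), 2 * np.sqrt(max(vals[0], 0)),
                        angle=ang, fill=False, color=color, lw=1.5)
            )
            ax.plot(*mean, "x" if color == "k" else "+", color=color, ms=10)
    if target_xy is not None:
        ax.plot(*target_xy, "o", color="red", ms=9, mfc="none", mew=2)
    return ax


def plot_occupancy(traj, layout, window_s=120.0, bins=30, ax=None):
    """Heatmap of probe-trial occupancy over the analysis window."""
    if ax is None:
        _, ax = plt.subplots(figsize=(6, 6))
    stop = np.searchsorted(traj.t, traj.t[0] + window_s, side="right")
    R = layout.radius
    h, xe, ye = np.histogram2d(
        traj.x[:stop], traj.y[:stop], bins=bins, range=[[-R, R], [-R, R]]
    )
    ax.imshow(h.T, origin="lower", extent=[-R, R, -R, R], cmap="magma")
    _arena_axes(ax, R)
    return ax


def report_figures(dataset, config, outdir):
    """Write the standard report figures for a pipeline run."""
    from .pipeline import analyze_trial_group

    layout = dataset.layout
    learning = [tr for tr in dataset.trials if not tr.probe]
    if learning:
        last = max(tr.trial_index for tr in learning)
        group = [tr for tr in learning if tr.trial_index == last]
        if len(group) >= 3:
            res = analyze_trial_group(group, layout, config)
            fig, axes = plt.subplots(1, 2, figsize=(12, 6))
            plot_displacement_field(
                res["ensemble"], layout, tev=res["tev"], target_xy=res["target_xy"],
                sd_mask_deg=config.tev.sd_threshold_deg, ax=axes[0],
            )
            plot_check_distribution(res["stats"], layout, res["target_xy"], ax=axes[1])
            fig.suptitle(f"trial {last}: displacement map and hole checks")
            fig.savefig(outdir / "displacement_and_checks.png", dpi=110)
            plt.close(fig)
    probes = [tr for tr in dataset.trials if tr.probe]
    if probes:
        fig, ax = plt.subplots(figsize=(6, 6))
        plot_occupancy(probes[0].trajectory, layout, config.probe.window_s, ax=ax)
        fig.savefig(outdir / "probe_occupancy.png", dpi=110)
        plt.close(fig)
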