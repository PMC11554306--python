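"""End-to-end analysis pipeline tying the stages together.

Stages: simulate (or load) a cohort -> detect hole checks -> per-trial
kinematic metrics and learning fit -> displacement fields (jackknifed over
mice, in the aligned frame) -> TEV per trial -> probe report -> figures.
Outputs are tidy tabular text files; a resolved copy of the configuration
and a structured log are written beside them, and the whole bundle is a
pure function of (inputs, config, seeds).
"""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import holecheck as hc
from .arena import (
    ArenaLayout,
    align_rotation_deg,
    align_trajectory,
    generate_hole_layout,
    read_layout,
    rel_of,
    write_layout,
)
from .config import PipelineConfig, dump_config
from .displacement import LatticeSpec, rasterize
from .kinematics import compute_trial_metrics, fit_learning_curve
from .probe import search_bias
from .simulate import BehaviorDataset, SimTrial, simulate_cohort
from .tev import TEVResult, build_null, compute_tev, jackknife_fields
from .trajectory import write_trajectory

logger = logging.getLogger("hfmaze")


def get_layout(config: PipelineConfig) -> ArenaLayout:
    if config.paths.layout:
        return read_layout(
            config.paths.layout,
            radius=config.arena.radius_cm,
            hole_capture_radius=config.arena.hole_capture_radius_cm,
        )
    return generate_hole_layout(
        seed=config.arena.seed,
        holes_per_quadrant=config.arena.holes_per_quadrant,
        min_spacing=config.arena.min_spacing_cm,
        wall_margin=config.arena.wall_margin_cm,
        radius=config.arena.radius_cm,
    )


def aligned_target_xy(layout: ArenaLayout, trial: SimTrial) -> np.ndarray:
    """True-target position in the common (entrance-aligned) frame."""
    deg = align_rotation_deg(trial.entrance_quadrant)
    return rel_of(layout.hole_xy(trial.target_hole_id), deg) if deg else layout.hole_xy(
        trial.target_hole_id
    )


def analyze_trial_group(
    trials: list[SimTrial],
    layout: ArenaLayout,
    config: PipelineConfig,
    null=None,
    origin=None,
) -> dict:
    """Jackknife displacement analysis + pooled check statistics for one
    trial index (one trial per mouse, aligned to the common frame)."""
    from dataclasses import replace as _dc_replace

    from scipy.spatial import cKDTree

    lattice = LatticeSpec(L=config.lattice.L, half_extent=layout.radius)
    base_tree = cKDTree(layout.holes)
    seqs = []
    pooled_events = []
    for tr in trials:
        atr = align_trajectory(tr.trajectory, tr.entrance_quadrant)
        seqs.append(rasterize(atr, lattice))
        alay = _aligned_layout(layout, tr.entrance_quadrant)
        events = hc.detect_checks(
            atr,
            alay,
            smoothing_window=config.detect.smoothing_window,
            proximity_radius=config.detect.proximity_radius_cm,
            speed_fraction=config.detect.speed_fraction,
            min_drop=config.detect.min_drop_cm_s,
            merge_window=config.detect.merge_window_s,
        )
        # event hole ids refer to the rotated layout; remap onto the base
        # layout's ids (the hole set is rotation invariant, so this is exact)
        if tr.entrance_quadrant != 1:
            remapped = []
            for ev in events:
                _, j = base_tree.query(alay.hole_xy(ev.hole_id))
                remapped.append(_dc_replace(ev, hole_id=int(layout.hole_ids[j])))
            events = remapped
        pooled_events.extend(events)
    target = aligned_target_xy(layout, trials[0])
    ensemble = jackknife_fields(seqs, L=lattice.L)
    stats = hc.spatial_stats(
        pooled_events, layout, target, near_radius=config.tev.near_radius_cm
    )
    if origin is None:
        origin = np.array([0.0, layout.radius])  # the aligned start
    if null is None:
        null = build_null(
            ensemble.N,
            n_draws=config.tev.n_draws,
            seed=config.tev.seed,
            centered=config.tev.centered_null,
        )
    tev = compute_tev(
        ensemble,
        stats,
        origin=origin,
        target=target,
        sd_threshold=config.tev.sd_threshold_deg,
        null=null,
    )
    return {"ensemble": ensemble, "stats": stats, "tev": tev, "events": pooled_events,
            "target_xy": target}


_ALIGNED_LAYOUT_CACHE: dict = {}


def _aligned_layout(layout: ArenaLayout, quadrant: int) -> ArenaLayout:
    """Layout rotated with the trajectory; the hole set is invariant, so the
    same layout object works, but hole ids must match rotated positions."""
    deg = align_rotation_deg(quadrant)
    if deg == 0:
        return layout
    key = (id(layout), deg)
    if key not in _ALIGNED_LAYOUT_CACHE:
        rot = np.stack([rel_of(p, deg) for p in layout.holes])
        _ALIGNED_LAYOUT_CACHE[key] = ArenaLayout(
            radius=layout.radius,
            holes=rot,
            hole_ids=layout.hole_ids,
            hole_capture_radius=layout.hole_capture_radius,
            min_spacing=layout.min_spacing,
            wall_margin=layout.wall_margin,
        )
    return _ALIGNED_LAYOUT_CACHE[key]


def metrics_table(dataset: BehaviorDataset) -> pd.DataFrame:
    layout = dataset.layout
    rows = []
    for tr in dataset.trials:
        start = layout.entrance(tr.entrance_quadrant)
        target_xy = layout.hole_xy(tr.target_hole_id)
        m = compute_trial_metrics(
            tr.trajectory, start, target_xy, layout.hole_capture_radius
        )
        rows.append(
            {
                "mouse_id": tr.mouse_id,
                "trial_index": tr.trial_index,
                "stage": tr.stage,
                "probe": tr.probe,
                "entrance_quadrant": tr.entrance_quadrant,
                "latency_s": m.latency_s,
                "censored": m.censored,
                "d_total_cm": m.d_total_cm,
                "d_target_cm": m.d_target_cm,
                "normalized_length": m.normalized_length,
                "mean_speed_cm_s": m.mean_speed_cm_s,
                "mean_heading_deviation_deg": m.mean_heading_deviation_deg,
                "mean_distance_to_food_line_cm": m.mean_distance_to_food_line_cm,
            }
        )
    return pd.DataFrame(rows)


def detect_table(dataset: BehaviorDataset, config: PipelineConfig) -> pd.DataFrame:
    frames = []
    for tr in dataset.trials:
        events = hc.detect_checks(
            tr.trajectory,
            dataset.layout,
            smoothing_window=config.detect.smoothing_window,
            proximity_radius=config.detect.proximity_radius_cm,
            speed_fraction=config.detect.speed_fraction,
            min_drop=config.detect.min_drop_cm_s,
            merge_window=config.detect.merge_window_s,
        )
        frames.append(
            hc.events_to_frame(
                events, mouse_id=tr.mouse_id, trial_index=tr.trial_index, stage=tr.stage
            )
        )
    return pd.concat(frames, ignore_index=True) if frames else pd.DataFrame()


def tev_table(
    dataset: BehaviorDataset, config: PipelineConfig, fields_dir=None
) -> pd.DataFrame:
    layout = dataset.layout
    learning = [tr for tr in dataset.trials if not tr.probe]
    rows = []
    by_key: dict = {}
    for tr in learning:
        by_key.setdefault((tr.stage, tr.trial_index), []).append(tr)
    null = None
    for (stage, t_idx), group in sorted(by_key.items()):
        if len(group) < 3:
            continue
        if null is None or null.N != len(group):
            null = build_null(
                len(group), n_draws=config.tev.n_draws, seed=config.tev.seed,
                centered=config.tev.centered_null,
            )
        res = analyze_trial_group(group, layout, config, null=null)
        tev: TEVResult = res["tev"]
        if fields_dir is not None:
            ens = res["ensemble"]
            L = ens.fields[0].L
            xs, ys = np.meshgrid(np.arange(1, L + 1), np.arange(1, L + 1), indexing="ij")
            site_sd = ens.site_angular_sd()
            pd.DataFrame(
                {
                    "x": xs.ravel(),
                    "y": ys.ravel(),
                    "Mh": ens.mean_M[..., 0].ravel(),
                    "Mv": ens.mean_M[..., 1].ravel(),
                    "site_sd_deg": site_sd.ravel(),
                }
            ).to_csv(Path(fields_dir) / f"field_{stage}_{t_idx:02d}.csv", index=False)
        rows.append(
            {
                "stage": stage,
                "trial_index": t_idx,
                "ux": tev.direction[0],
                "uy": tev.direction[1],
                "D_cm": tev.magnitude,
                "sigma_D_cm": tev.sigma_D,
                "sd_deg": tev.angular_sd_deg,
                "p": tev.p_directionality,
                "p_source": tev.p_source,
                "deviation_deg": tev.deviation_deg,
                "branch": tev.branch,
            }
        )
    return pd.DataFrame(rows)


def probe_table(dataset: BehaviorDataset, config: PipelineConfig) -> pd.DataFrame:
    layout = dataset.layout
    rows = []
    for tr in dataset.trials:
        if not tr.probe:
            continue
        bias = search_bias(
            tr.trajectory,
            layout.hole_xy(tr.target_hole_id),
            layout,
            window=config.probe.window_s,
            square_half_width=config.probe.square_half_width_cm,
        )
        rows.append(
            {
                "mouse_id": tr.mouse_id,
                "trial_index": tr.trial_index,
                "stage": tr.stage,
                "pct_target_square": bias.percent_time_target_square,
                "pct_rel90": bias.percent_time_rel_squares[0],
                "pct_rel180": bias.percent_time_rel_squares[1],
                "pct_rel270": bias.percent_time_rel_squares[2],
                "pct_q1": bias.percent_time_quadrants[0],
                "pct_q2": bias.percent_time_quadrants[1],
                "pct_q3": bias.percent_time_quadrants[2],
                "pct_q4": bias.percent_time_quadrants[3],
            }
        )
    return pd.DataFrame(rows)


def learning_fit_row(metrics: pd.DataFrame, stage: str = "A") -> dict:
    sub = metrics[(metrics["stage"] == stage) & (~metrics["probe"])]
    mean_d = sub.groupby("trial_index")["d_total_cm"].mean()
    fit = fit_learning_curve(mean_d.to_numpy(), trials=mean_d.index.to_numpy(float))
    return {"stage": stage, "B": fit.B, "K": fit.K, "K_sd": fit.K_sd, "CV": fit.CV,
            "unstable": fit.unstable}


def run_pipeline(config: PipelineConfig, outdir=None) -> dict:
    """Run every stage and write the report bundle; returns the tables."""
    t0 = time.time()
    outdir = Path(outdir or config.paths.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    timings = {}

    def stage(name):
        timings[name] = time.time()
        logger.info("stage %s", name)

    stage("layout")
    layout = get_layout(config)
    write_layout(layout, outdir / "layout.csv")

    stage("simulate")
    dataset = simulate_cohort(config.sim, layout)
    trajdir = outdir / "trajectories"
    trajdir.mkdir(exist_ok=True)
    manifest_rows = []
    for k, tr in enumerate(dataset.trials):
        fname = f"trial_{k:04d}_{tr.mouse_id}_{tr.stage}{tr.trial_index}.csv"
        write_trajectory(tr.trajectory, trajdir / fname)
        manifest_rows.append(
            {
                "file": f"trajectories/{fname}",
                "mouse_id": tr.mouse_id,
                "trial_index": tr.trial_index,
                "entrance_quadrant": tr.entrance_quadrant,
                "protocol_stage": tr.stage,
                "target_hole_id": tr.target_hole_id,
                "probe_flag": tr.probe,
            }
        )
    pd.DataFrame(manifest_rows).to_csv(outdir / "manifest.csv", index=False)

    stage("detect")
    checks = detect_table(dataset, config)
    checks.to_csv(outdir / "hole_checks.csv", index=False)

    stage("metrics")
    metrics = metrics_table(dataset)
    metrics.to_csv(outdir / "trial_metrics.csv", index=False)
    fits = pd.DataFrame(
        [learning_fit_row(metrics, stage=s) for s in sorted(metrics["stage"].unique())
         if not metrics[(metrics["stage"] == s) & (~metrics["probe"])].empty
         and metrics[(metrics["stage"] == s) & (~metrics["probe"])]["trial_index"].nunique() >= 4]
    )
    fits.to_csv(outdir / "learning_fit.csv", index=False)

    stage("displacement+tev")
    fields_dir = outdir / "fields"
    fields_dir.mkdir(exist_ok=True)
    tevs = tev_table(dataset, config, fields_dir=fields_dir)
    tevs.to_csv(outdir / "tev.csv", index=False)

    stage("probe")
    probes = probe_table(dataset, config)
    probes.to_csv(outdir / "probe_report.csv", index=False)

    if config.make_figures:
        stage("figures")
        from . import plots

        plots.report_figures(dataset, config, outdir)

    dump_config(config, outdir / "resolved_config.yaml")
    order = list(timings)
    log = {
        name: round((timings[order[i + 1]] if i + 1 < len(order) else time.time()) - t,
                    3)
        for i, (name, t) in enumerate(timings.items())
    }
    with open(outdir / "run_log.json", "w") as fh:
        json.dump({"stage_seconds": log, "total_seconds": round(time.time() - t0, 3)}, fh,
                  indent=2)
    return {
        "layout": layout,
        "dataset": dataset,
        "checks": checks,
        "metrics": metrics,
        "fits": fits,
        "tev": tevs,
        "probes": probes,
        "outdir": outdir,
    }
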