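"""Synthetic cohorts of maze trajectories with embedded hole checks.

The generator stands in for tracked animal data and reproduces the
statistical structure the analyses assume: early trials are dominated by
wall-following (thigmotactic) random search; across trials an increasing
goal weight w = 1 - exp(-trial / learning_timescale) shifts behavior
toward near-direct runs to a noisy *believed* target (path-integration
error), so the total distance decays as d_target * (1 + c * exp(-trial/K)).
Hole passes trigger brief check dwells (0.3-1.0 s pauses with a smooth
velocity dip) whose probability concentrates near the believed target as
skill grows.  Trials end at target capture or timeout.

Motion model: discrete-time heading process with Gaussian angular
innovation (a correlated random walk), per-segment speed draws from a
skill-interpolated distribution, and specular wall reflection.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .arena import ArenaLayout, align_rotation_deg, rel_of, select_target
from .errors import ConfigError
from .holecheck import HoleCheckEvent
from .trajectory import TrialMeta, Trajectory

PROTOCOLS = ("static", "random", "two_target", "rotated_probe")


@dataclass(frozen=True)
class SimConfig:
    """Study-condition parameters of the synthetic cohort generator."""

    n_mice: int = 8
    n_trials: int = 14
    sample_rate: float = 30.0            # Hz
    protocol: str = "static"
    learning_timescale: float = 5.0      # trials
    path_integration_noise_deg: float = 4.0   # angular S.D. on the believed target
    path_integration_noise_cm: float = 3.0    # radial S.D. on the believed target
    noise_growth_cm_per_m: float = 0.3   # believed-target drift per meter walked
    speed_early: float = 6.0             # cm/s mean, naive animals
    speed_late: float = 17.0             # cm/s mean, trained animals
    check_rate_baseline: float = 1.0     # checks per meter traveled, baseline
    check_concentration: float = 18.0    # cm; checks cluster within this of the believed target
    check_target_boost: float = 8.0      # peak rate multiplier at the believed target
    thigmotaxis_weight: float = 0.7      # early wall-following tendency, 0-1
    search_excess_early: float = 11.0    # trial-1 excess path in units of d_target
    tracking_noise_cm: float = 0.08      # nose-point measurement jitter S.D.
    timeout: float = 1200.0              # s (20 min trials)
    probe_duration: float = 120.0        # s (2 min probe window)
    n_trials_b: int = 8                  # stage-B trials in the two-target protocol
    rotation_probe_deg: float = 180.0
    seed: int = 0

    def validate(self) -> None:
        if self.sample_rate <= 0:
            raise ConfigError("sample_rate must be positive")
        if self.protocol not in PROTOCOLS:
            raise ConfigError(f"unsupported protocol {self.protocol!r}")
        for name in ("n_mice", "n_trials", "n_trials_b"):
            if getattr(self, name) < 1:
                raise ConfigError(f"{name} must be >= 1")
        for name in (
            "learning_timescale", "path_integration_noise_deg",
            "path_integration_noise_cm", "noise_growth_cm_per_m", "speed_early",
            "speed_late", "check_rate_baseline", "check_concentration",
            "check_target_boost", "search_excess_early", "timeout",
            "probe_duration", "tracking_noise_cm",
        ):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be non-negative")
        if not 0.0 <= self.thigmotaxis_weight <= 1.0:
            raise ConfigError("thigmotaxis_weight must be in [0, 1]")
        if self.rotation_probe_deg % 90 != 0:
            raise ConfigError("rotation_probe_deg must be a multiple of 90")


@dataclass(frozen=True)
class SimTrial:
    trajectory: Trajectory
    events: list            # ground-truth HoleCheckEvent (method=0)
    mouse_id: str
    trial_index: int
    entrance_quadrant: int
    stage: str              # "A", "B", "probe", ...
    target_hole_id: int
    believed_xy: np.ndarray
    probe: bool


@dataclass(frozen=True)
class BehaviorDataset:
    config: SimConfig
    layout: ArenaLayout
    trials: list

    def select(self, **kv) -> list:
        out = self.trials
        for k, v in kv.items():
            out = [tr for tr in out if getattr(tr, k) == v]
        return out


class _HoleGrid:
    """Cheap fixed-grid lookup of holes within a query radius."""

    def __init__(self, layout: ArenaLayout, radius: float = 3.0, cell: float = 6.0):
        self.cell = cell
        self.radius = radius
        self.layout = layout
        reach = radius + cell * math.sqrt(2) / 2 + 1e-9
        self.table: dict[tuple[int, int], np.ndarray] = {}
        cx = np.floor(layout.holes[:, 0] / cell).astype(int)
        cy = np.floor(layout.holes[:, 1] / cell).astype(int)
        lo_x, hi_x = cx.min() - 2, cx.max() + 2
        lo_y, hi_y = cy.min() - 2, cy.max() + 2
        for ix in range(lo_x, hi_x + 1):
            for iy in range(lo_y, hi_y + 1):
                center = np.array([(ix + 0.5) * cell, (iy + 0.5) * cell])
                d = np.linalg.norm(layout.holes - center, axis=1)
                idx = np.flatnonzero(d <= reach)
                if idx.size:
                    self.table[(ix, iy)] = idx

    def nearest_within(self, x: float, y: float):
        """(hole_index, distance) of the nearest hole within ``radius``, else None."""
        key = (math.floor(x / self.cell), math.floor(y / self.cell))
        idx = self.table.get(key)
        if idx is None:
            return None
        hx = self.layout.holes[idx]
        d = np.hypot(hx[:, 0] - x, hx[:, 1] - y)
        j = int(np.argmin(d))
        if d[j] <= self.radius:
            return int(idx[j]), float(d[j])
        return None


def _wrap_rad(a: float) -> float:
    return (a + math.pi) % (2 * math.pi) - math.pi


def simulate_trial(
    config: SimConfig,
    layout: ArenaLayout,
    mouse_skill: float,
    entrance_quadrant: int,
    target_hole_id: int,
    rng: np.random.Generator,
    believed_targets=None,
    probe: bool = False,
    speed_skill: float | None = None,
    meta: TrialMeta | None = None,
    mouse_id: str = "m0",
    trial_index: int = 1,
    stage: str = "A",
) -> SimTrial:
    """Simulate one trial; returns the trajectory and ground-truth checks.

    ``mouse_skill`` in [0, 1] is the goal weight (0 = memoryless search,
    1 = direct run to the believed target).  ``believed_targets`` may
    override the believed waypoint(s); by default a single waypoint is the
    true target corrupted by the configured path-integration noise.
    Probe trials never capture and run for ``probe_duration`` seconds.
    """
    config.validate()
    if not 0.0 <= mouse_skill <= 1.0:
        raise ConfigError("mouse_skill must be in [0, 1]")
    if speed_skill is None:
        speed_skill = mouse_skill
    dt = 1.0 / config.sample_rate
    R = layout.radius
    start = layout.entrance(entrance_quadrant).astype(float)
    target_xy = layout.hole_xy(target_hole_id)
    d_target = float(np.linalg.norm(target_xy - start))

    if believed_targets is None:
        # the target estimate sharpens with training: repeated reinforced
        # runs trim the accumulated path-integration error
        noise_scale = max(1.0 - 0.75 * mouse_skill, 0.5)
        vec = target_xy - start
        ang = math.atan2(vec[1], vec[0]) + math.radians(
            rng.normal(0.0, config.path_integration_noise_deg * noise_scale)
        )
        dist = np.linalg.norm(vec) + rng.normal(
            0.0, config.path_integration_noise_cm * noise_scale
        )
        believed_targets = [start + max(dist, 1.0) * np.array([math.cos(ang), math.sin(ang)])]
    waypoints = [np.asarray(w, dtype=float) for w in believed_targets]

    # exploratory budget before the goal run engages
    if mouse_skill <= 0.0:
        budget = math.inf
    else:
        budget = (
            config.search_excess_early
            * d_target
            * (1.0 - mouse_skill)
            * math.exp(rng.normal(0.0, 0.25))
        )

    v_mean = config.speed_early + speed_skill * (config.speed_late - config.speed_early)
    # cruise speed stays within [0.6, 1.4] x mean so that the trial maximum
    # never dwarfs ordinary running (hole-check dips are the only slow-downs)
    def _draw_speed(rng=None, _v=v_mean):
        r = rng
        return float(np.clip(r.normal(_v, 0.15 * _v), 0.6 * _v, 1.4 * _v))
    duration = config.probe_duration if probe else config.timeout
    n_max = int(round(duration * config.sample_rate)) + 1

    grid = _HoleGrid(layout, radius=3.6)
    turn_sd = math.radians(90.0) * math.sqrt(dt)  # heading diffusion 90 deg / sqrt(s)
    # wall hugging fades with familiarity (running speed tracks familiarity)
    thig = config.thigmotaxis_weight * (1.0 - speed_skill)

    pos = start.copy()
    # nudge inside the wall so the walk has room
    pos *= (R - 1.0) / max(np.linalg.norm(pos), 1e-9)
    heading = math.atan2(-pos[1], -pos[0])  # facing the arena center
    phase = "explore" if budget > 0 else "goal"
    wp_i = 0
    local_until = -1.0   # probe linger deadline
    excursion_until = -1.0  # probe away-from-site excursion deadline
    local_started = 0.0  # for the expanding local-search radius
    local_goal = None    # current sub-goal of the local search
    explore_goal = None  # interior waypoint visited during random search
    explore_redraw = 0.0
    speed = _draw_speed(rng)
    xs, ys = [pos[0]], [pos[1]]
    events: list[HoleCheckEvent] = []
    cumlen = 0.0
    walked_m = 0.0
    drift = np.zeros(2)
    last_check_t = -10.0
    last_hole_t: dict[int, float] = {}
    zone_hole = -1  # hole whose trigger zone we are currently inside
    dwell_left = 0
    dwell_hole = None
    capture_r = layout.hole_capture_radius
    p_enc = min(0.95, config.check_rate_baseline / 5.0)  # ~5 hole encounters per meter

    i = 1
    while i < n_max:
        t_now = i * dt
        if dwell_left > 0:
            # check dwell: settle onto the hole and hold nearly still
            hxy = layout.holes[dwell_hole]
            new = pos + 0.35 * (hxy - pos) + rng.normal(0.0, 0.02, size=2)
            dwell_left -= 1
            if dwell_left == 0:
                heading = _wrap_rad(heading + rng.normal(0.0, 0.4))
        else:
            # refresh the per-segment speed about twice a second
            if i % 15 == 0:
                speed = _draw_speed(rng)
            if phase == "explore":
                r = np.linalg.norm(pos)
                if thig > 0 and r > 0.72 * R and rng.uniform() < thig:
                    # follow the wall along the current orientation sense
                    tangent = math.atan2(pos[0], -pos[1])  # CW tangent
                    if math.cos(heading - tangent) < 0:
                        tangent = _wrap_rad(tangent + math.pi)
                    heading += 0.4 * _wrap_rad(tangent - heading)
                else:
                    # occasional interior excursions keep search coverage broad
                    if explore_goal is None or t_now >= explore_redraw or np.linalg.norm(explore_goal - pos) < 4.0:
                        # outward-biased endpoints flatten the center
                        # oversampling that straight legs between
                        # area-uniform points would produce
                        rr = (R - 4.0) * rng.uniform() ** 0.25
                        th = rng.uniform(0.0, 2 * math.pi)
                        explore_goal = np.array([rr * math.cos(th), rr * math.sin(th)])
                        explore_redraw = t_now + 3.5
                    to_g = explore_goal - pos
                    heading += 0.15 * _wrap_rad(math.atan2(to_g[1], to_g[0]) - heading)
                # jagged search: frequent sharp turns and full reversals
                if rng.uniform() < 0.4 * dt:
                    heading = _wrap_rad(heading + math.pi + rng.normal(0.0, 0.6))
                    explore_goal = None
                heading = _wrap_rad(heading + rng.normal(0.0, turn_sd))
                if probe and excursion_until > 0 and t_now >= excursion_until:
                    phase = "goal"
                    excursion_until = -1.0
                elif cumlen >= budget and wp_i < len(waypoints):
                    phase = "goal"
            elif phase == "goal":
                wp = waypoints[wp_i] + drift
                to_wp = wp - pos
                desired = math.atan2(to_wp[1], to_wp[0])
                heading += 0.5 * _wrap_rad(desired - heading)
                heading = _wrap_rad(heading + rng.normal(0.0, 0.6 * turn_sd))
                if np.linalg.norm(to_wp) < 3.0:
                    phase = "local"
                    local_started = t_now
                    local_goal = None
                    if probe:
                        local_until = t_now + rng.uniform(8.0, 16.0)
            else:  # local search: visit holes fanning out around the waypoint
                wp = waypoints[wp_i] + drift
                spread = min(6.0 + 0.3 * (t_now - local_started), 20.0)
                if local_goal is None or np.linalg.norm(local_goal - pos) < 2.0:
                    d_h = np.linalg.norm(layout.holes - wp, axis=1)
                    cand = np.flatnonzero(d_h <= spread)
                    if cand.size:
                        local_goal = layout.holes[rng.choice(cand)] + rng.normal(0.0, 1.0, 2)
                    else:
                        local_goal = wp + rng.normal(0.0, spread, size=2)
                    if np.linalg.norm(local_goal) > R - 2.0:
                        local_goal *= (R - 2.0) / np.linalg.norm(local_goal)
                to_g = local_goal - pos
                heading += 0.5 * _wrap_rad(math.atan2(to_g[1], to_g[0]) - heading)
                heading = _wrap_rad(heading + rng.normal(0.0, 0.8 * turn_sd))
                if probe and t_now >= local_until:
                    local_goal = None
                    if wp_i < len(waypoints) - 1:
                        wp_i += 1
                        phase = "goal"
                    else:
                        # brief excursion away, then return to the believed
                        # site: probe searches keep re-visiting it
                        phase = "explore"
                        excursion_until = t_now + rng.uniform(8.0, 18.0)
            step_speed = 0.6 * speed if phase == "local" else speed
            new = pos + step_speed * dt * np.array([math.cos(heading), math.sin(heading)])
            # specular reflection at the wall
            rn = np.linalg.norm(new)
            if rn > R - 0.5:
                normal = new / rn
                vel = new - pos
                vel = vel - 2.0 * (vel @ normal) * normal
                heading = math.atan2(vel[1], vel[0])
                new = pos + vel
                if np.linalg.norm(new) > R - 0.4:
                    new *= (R - 0.6) / np.linalg.norm(new)

            # hole encounters can trigger a check dwell; the Bernoulli draw
            # happens once per pass (on entering a hole's trigger zone)
            hit = grid.nearest_within(new[0], new[1])
            bel_now = waypoints[min(wp_i, len(waypoints) - 1)] + drift
            # trained animals cast a wider sensory net close to where they
            # expect the food, checking holes slightly off their path
            r_trig = 2.0 + 2.0 * mouse_skill * math.exp(
                -np.linalg.norm(new - bel_now) / 20.0
            )
            if hit is None or hit[1] >= r_trig:
                zone_hole = -1
            elif dwell_left == 0:
                h_idx, h_d = hit
                entering = h_idx != zone_hole
                zone_hole = h_idx
                if entering and t_now - last_hole_t.get(h_idx, -10.0) > 2.0:
                    d_bel = np.linalg.norm(layout.holes[h_idx] - bel_now)
                    # learning trades indiscriminate checking for focused
                    # checking near the believed target
                    p = p_enc + (
                        p_enc
                        * config.check_target_boost
                        * mouse_skill
                        * math.exp(-((d_bel / config.check_concentration) ** 2))
                    )
                    if rng.uniform() < min(p, 0.95):
                        dwell_left = int(rng.uniform(0.3, 1.0) * config.sample_rate)
                        dwell_hole = h_idx
                        last_check_t = t_now
                        last_hole_t[h_idx] = t_now
                        hx, hy = layout.holes[h_idx]
                        events.append(
                            HoleCheckEvent(
                                time_index=i + dwell_left // 2,
                                time_s=(i + dwell_left // 2) * dt,
                                hole_id=int(layout.hole_ids[h_idx]),
                                x=float(hx),
                                y=float(hy),
                                method=0,
                            )
                        )

        step = np.linalg.norm(new - pos)
        cumlen += step
        walked_m += step / 100.0
        if config.noise_growth_cm_per_m > 0 and step > 0:
            drift += rng.normal(0.0, config.noise_growth_cm_per_m, size=2) * math.sqrt(
                step / 100.0
            )
        pos = new
        xs.append(pos[0])
        ys.append(pos[1])
        i += 1
        if not probe and np.linalg.norm(pos - target_xy) <= capture_r:
            # food found: the nose is in the target hole and the mouse
            # settles to eat, the trial's final (rewarded) hole check
            events = [
                ev
                for ev in events
                if not (ev.hole_id == target_hole_id and i * dt - ev.time_s <= 1.0)
            ]
            events.append(
                HoleCheckEvent(
                    time_index=min(i + 5, n_max - 1),
                    time_s=min(i + 5, n_max - 1) * dt,
                    hole_id=int(target_hole_id),
                    x=float(target_xy[0]),
                    y=float(target_xy[1]),
                    method=0,
                )
            )
            for _ in range(int(1.5 * config.sample_rate)):
                pos = pos + 0.35 * (target_xy - pos) + rng.normal(0.0, 0.02, size=2)
                xs.append(pos[0])
                ys.append(pos[1])
                i += 1
            break

    n = len(xs)
    x_arr = np.asarray(xs)
    y_arr = np.asarray(ys)
    if config.tracking_noise_cm > 0:
        # nose-point measurement jitter; clip back into the arena disc
        x_arr = x_arr + rng.normal(0.0, config.tracking_noise_cm, n)
        y_arr = y_arr + rng.normal(0.0, config.tracking_noise_cm, n)
        rr = np.hypot(x_arr, y_arr)
        out = rr > R
        if out.any():
            x_arr[out] *= R / rr[out]
            y_arr[out] *= R / rr[out]
    # a capture can cut a dwell short; keep event indices inside the trace
    events = [
        replace(ev, time_index=min(ev.time_index, n - 1), time_s=min(ev.time_s, (n - 1) * dt))
        for ev in events
    ]
    meta = meta or TrialMeta(
        mouse_id=mouse_id,
        trial_index=trial_index,
        entrance_quadrant=entrance_quadrant,
        protocol_stage=stage,
        target_hole_id=target_hole_id,
        probe_flag=probe,
    )
    traj = Trajectory(t=np.arange(n) * dt, x=x_arr, y=y_arr, metadata=meta)
    return SimTrial(
        trajectory=traj,
        events=events,
        mouse_id=meta.mouse_id,
        trial_index=meta.trial_index,
        entrance_quadrant=entrance_quadrant,
        stage=stage,
        target_hole_id=target_hole_id,
        believed_xy=waypoints[0],
        probe=probe,
    )


def _balanced_entrances(n_trials: int, rng: np.random.Generator) -> list[int]:
    """One mouse's entrance schedule: balanced counts, no consecutive repeats."""
    base = [1 + k % 4 for k in range(n_trials)]
    for _ in range(10_000):
        perm = list(rng.permutation(base))
        if all(a != b for a, b in zip(perm[:-1], perm[1:])):
            return perm
    raise RuntimeError("could not schedule entrances")  # pragma: no cover


def _batch_entrances(
    n_mice: int, n_trials: int, rng: np.random.Generator
) -> list[list[int]]:
    """Cohort entrance schedules in experiment batches of four.

    Within each batch of four mice, every trial uses all four entrances
    (one mouse per quadrant), mice never repeat their previous entrance,
    and counts stay balanced per mouse.  A remainder batch smaller than
    four falls back to independent balanced schedules.
    """
    def latin_square() -> np.ndarray:
        # random 4x4 Latin square: permute symbols, rows and columns of the
        # cyclic square (vertical neighbors always differ within a square)
        base = (np.arange(4)[:, None] + np.arange(4)[None, :]) % 4
        sym = rng.permutation(4)
        sq = sym[base]
        return sq[rng.permutation(4)][:, rng.permutation(4)] + 1

    schedules: list[list[int]] = [[] for _ in range(n_mice)]
    full = (n_mice // 4) * 4
    n_blocks = -(-n_trials // 4)
    for b in range(0, full, 4):
        rows: list[np.ndarray] = []
        while len(rows) < n_trials:
            for _ in range(1000):
                sq = latin_square()
                if not rows or np.all(sq[0] != rows[-1]):
                    break
            rows.extend(list(sq))
        for t in range(n_trials):
            for j in range(4):
                schedules[b + j].append(int(rows[t][j]))
    for m in range(full, n_mice):
        schedules[m] = _balanced_entrances(n_trials, rng)
    return schedules


def _skill(trial: int, timescale: float) -> float:
    return 1.0 - math.exp(-trial / timescale)


def simulate_cohort(config: SimConfig, layout: ArenaLayout) -> BehaviorDataset:
    """Full protocol schedule for a cohort of ``n_mice`` mice.

    static: fixed entrance, ``n_trials`` learning trials.
    random: per-trial entrance shuffled (balanced, no immediate repeats);
        directional skill stays 0 (direction cannot be learned), running
        speed still improves with familiarity.
    two_target: stage A trials, stage B trials, then a no-food B-to-A probe.
    rotated_probe: static training plus a final probe from a rotated
        entrance with the believed target carried in the egocentric frame
        (the mouse heads to the REL of the trained target).
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    K = config.learning_timescale
    trials: list[SimTrial] = []

    if config.protocol == "random":
        target = select_target(layout, "random", layout.entrances)
        schedules = _batch_entrances(config.n_mice, config.n_trials, rng)
        for m in range(config.n_mice):
            for t in range(1, config.n_trials + 1):
                trials.append(
                    simulate_trial(
                        config, layout, 0.0, schedules[m][t - 1], target,
                        rng, speed_skill=_skill(t, K),
                        mouse_id=f"m{m}", trial_index=t, stage="A",
                    )
                )
    elif config.protocol in ("static", "rotated_probe"):
        entrance = 1
        if config.protocol == "rotated_probe":
            target = _rotation_discriminable_target(
                layout, entrance, config.rotation_probe_deg
            )
        else:
            target = select_target(layout, "static", layout.entrance(entrance))
        for m in range(config.n_mice):
            for t in range(1, config.n_trials + 1):
                trials.append(
                    simulate_trial(
                        config, layout, _skill(t, K), entrance, target, rng,
                        mouse_id=f"m{m}", trial_index=t, stage="A",
                    )
                )
            if config.protocol == "rotated_probe":
                rot = config.rotation_probe_deg % 360
                probe_entrance = int((entrance - 1 + rot // 90) % 4) + 1
                # egocentric carry-over: the believed target rotates with the start
                skill = _skill(config.n_trials, K)
                target_xy = layout.hole_xy(target)
                vec = target_xy - layout.entrance(entrance)
                ang = math.atan2(vec[1], vec[0]) + math.radians(
                    rng.normal(0.0, config.path_integration_noise_deg)
                )
                dist = np.linalg.norm(vec) + rng.normal(
                    0.0, config.path_integration_noise_cm
                )
                believed_trained = layout.entrance(entrance) + max(dist, 1.0) * np.array(
                    [math.cos(ang), math.sin(ang)]
                )
                believed_probe = rel_of(believed_trained, rot)
                trials.append(
                    simulate_trial(
                        config, layout, skill, probe_entrance, target, rng,
                        believed_targets=[believed_probe], probe=True,
                        mouse_id=f"m{m}", trial_index=config.n_trials + 1,
                        stage="probe",
                    )
                )
    elif config.protocol == "two_target":
        entrance = 1
        start = layout.entrance(entrance)
        target_a = select_target(layout, "static", start)
        target_b = _second_target(layout, start, target_a)
        for m in range(config.n_mice):
            for t in range(1, config.n_trials + 1):
                trials.append(
                    simulate_trial(
                        config, layout, _skill(t, K), entrance, target_a, rng,
                        mouse_id=f"m{m}", trial_index=t, stage="A",
                    )
                )
            for t in range(1, config.n_trials_b + 1):
                trials.append(
                    simulate_trial(
                        config, layout, _skill(t, K), entrance, target_b, rng,
                        speed_skill=1.0,
                        mouse_id=f"m{m}", trial_index=config.n_trials + t, stage="B",
                    )
                )
            # no-food probe: visit believed B, then shortcut to believed A
            bel = []
            for tgt in (target_b, target_a):
                xy = layout.hole_xy(tgt)
                bel.append(xy + rng.normal(0.0, config.path_integration_noise_cm, 2))
            trials.append(
                simulate_trial(
                    config, layout, 1.0, entrance, target_a, rng,
                    believed_targets=bel, probe=True, speed_skill=1.0,
                    mouse_id=f"m{m}",
                    trial_index=config.n_trials + config.n_trials_b + 1,
                    stage="probe",
                )
            )
    else:  # pragma: no cover - validate() already rejects
        raise ConfigError(f"unsupported protocol {config.protocol!r}")
    return BehaviorDataset(config=config, layout=layout, trials=trials)


def _rotation_discriminable_target(
    layout: ArenaLayout, entrance: int, rotation_deg: float, min_sep_deg: float = 20.0
) -> int:
    """Static-protocol target whose target vector is angularly separable
    from its rotationally equivalent counterpart.

    A rotated-probe readout compares the direction to the trained target
    with the direction to its REL; targets too close to the start-center
    axis make those directions indistinguishable, so the protocol demands
    a minimum angular separation (the apparatus target placements were
    chosen with the same care).
    """
    start = layout.entrance(entrance)
    wall_d = layout.radius - np.linalg.norm(layout.holes, axis=1)
    start_d = np.linalg.norm(layout.holes - start, axis=1)
    for hid in layout.hole_ids:
        xy = layout.hole_xy(int(hid))
        if layout.radius - np.linalg.norm(xy) <= 35.0:
            continue
        if np.linalg.norm(xy - start) <= 60.0:
            continue
        relxy = rel_of(xy, rotation_deg % 360)
        a = xy - start
        b = relxy - start
        cosang = a @ b / (np.linalg.norm(a) * np.linalg.norm(b))
        if math.degrees(math.acos(max(min(cosang, 1.0), -1.0))) >= min_sep_deg:
            return int(hid)
    raise ConfigError(
        "this hole layout offers no rotated-probe target whose REL direction "
        f"is separable by {min_sep_deg} degrees; regenerate the arena"
    )


def _second_target(layout: ArenaLayout, start, target_a: int) -> int:
    """Stage-B food hole: qualifies like a static target, well away from A
    and not mirror-symmetric to it about the start-center line."""
    a_xy = layout.hole_xy(target_a)
    u = start / np.linalg.norm(start)
    for hid in layout.hole_ids:
        if hid == target_a:
            continue
        xy = layout.hole_xy(int(hid))
        if layout.radius - np.linalg.norm(xy) <= 25.0:
            continue
        if np.linalg.norm(xy - np.asarray(start, float)) <= 50.0:
            continue
        if np.linalg.norm(xy - a_xy) <= 25.0:
            continue
        mirror = xy - 2 * float(xy @ np.array([-u[1], u[0]])) * np.array([-u[1], u[0]])
        if np.linalg.norm(mirror - a_xy) <= 10.0:
            continue
        return int(hid)
    raise ConfigError("no qualifying stage-B target in this layout")
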