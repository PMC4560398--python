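"""Scripted (non-evolved) controllers and the scripted trial runner.

Scripted policies exercise every measure without running evolution:
a leader heading straight to a zone, colour-following followers,
orbiting robots, random walkers.  Policies may read the true world
state (they are test instruments, not evolvable controllers); the
physics they are run under — kinematics, collision handling, sensors,
zone scoring — is exactly the one used for evolved teams.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .io import TrialLog
from .world import ArenaConfig, COLOUR_NORM, N_ROBOTS


@dataclass
class ScriptedController:
    """A named wheel-speed policy.

    policy ids: ``stationary``, ``constant`` (fixed v_left/v_right),
    ``goto_zone`` (steer to zone ``k``), ``goto_nearest_zone``,
    ``follow_colour`` (steer to robot ``k``), ``orbit`` (circle of given
    radius around ``center``), ``random_walk`` (seeded, piecewise-
    constant controls), ``spin`` (rotate in place).
    """

    policy: str
    k: int = 0
    v_left: float = 0.0
    v_right: float = 0.0
    speed: float = 1.0
    center: tuple = (55.0, 55.0)
    radius: float = 10.0
    hold: int = 20          # random_walk: steps between redraws
    gain: float = 2.0       # steering gain for pursuit policies
    stop_radius: float = 0.0  # goto policies: park when this close

    def __post_init__(self):
        self._rw_state = None

    def controls(self, t: int, i: int, poses: np.ndarray,
                 config: ArenaConfig, rng: np.random.Generator
                 ) -> tuple[float, float]:
        vmax = config.wheel_speed_max
        x, y, th = poses[i]
        if self.policy == "stationary":
            return 0.0, 0.0
        if self.policy == "constant":
            return self.v_left, self.v_right
        if self.policy == "spin":
            return -self.speed, self.speed
        if self.policy == "goto_zone":
            tx, ty = config.zones[self.k]
            if np.hypot(tx - x, ty - y) <= self.stop_radius:
                return 0.0, 0.0
            return self._pursue(x, y, th, tx, ty, vmax)
        if self.policy == "goto_nearest_zone":
            zones = config.zones
            d2 = ((zones - [x, y]) ** 2).sum(axis=1)
            tx, ty = zones[int(np.argmin(d2))]
            if np.hypot(tx - x, ty - y) <= self.stop_radius:
                return 0.0, 0.0
            return self._pursue(x, y, th, tx, ty, vmax)
        if self.policy == "follow_colour":
            tx, ty = poses[self.k, :2]
            d = np.hypot(tx - x, ty - y)
            if d <= 1.5 * config.robot_diameter:
                return 0.0, 0.0  # standoff above the collision distance
            return self._pursue(x, y, th, tx, ty, vmax)
        if self.policy == "orbit":
            cx, cy = self.center
            # steer to the tangent of the circle around (cx, cy)
            ang = np.arctan2(y - cy, x - cx)
            tgt = ang + 0.35  # rad ahead on the circle (CCW orbit)
            tx = cx + self.radius * np.cos(tgt)
            ty = cy + self.radius * np.sin(tgt)
            return self._pursue(x, y, th, tx, ty, vmax)
        if self.policy == "random_walk":
            if self._rw_state is None or t % self.hold == 0:
                self._rw_state = (float(rng.uniform(-vmax, vmax)),
                                  float(rng.uniform(-vmax, vmax)))
            return self._rw_state
        raise ValueError(f"unknown policy {self.policy!r}")

    def _pursue(self, x, y, th, tx, ty, vmax):
        err = _kernels.wrap_pi(np.arctan2(ty - y, tx - x) - th)
        v = self.speed * vmax * max(0.0, np.cos(err))
        turn = np.clip(self.gain * err, -1.0, 1.0) * vmax
        vl = np.clip(v - turn, -vmax, vmax)
        vr = np.clip(v + turn, -vmax, vmax)
        return float(vl), float(vr)


def run_scripted_trial(policies, config: ArenaConfig, seed: int,
                       init_poses: np.ndarray | None = None,
                       pinned: np.ndarray | None = None,
                       pin_pose: np.ndarray | None = None,
                       active: np.ndarray | None = None,
                       steps: int | None = None,
                       record_sensors: bool = True,
                       resolve_collisions: bool = True) -> TrialLog:
    """Run one trial under scripted policies, logging like an evolved trial.

    ``init_poses`` (4, 3) fixes the starting poses; otherwise placement
    is uniform random exactly as in evolved trials.  Set
    ``resolve_collisions=False`` for fixtures whose closed-form geometry
    must not be perturbed by random repositioning.
    """
    if len(policies) != N_ROBOTS:
        raise ValueError("one policy per robot required")
    if steps is None:
        steps = config.steps_per_trial
    if pinned is None:
        pinned = np.zeros(N_ROBOTS, dtype=bool)
    if active is None:
        active = np.ones(N_ROBOTS, dtype=bool)
    pinned = np.asarray(pinned, dtype=bool)
    active = np.asarray(active, dtype=bool)
    rng = np.random.default_rng(seed)

    xs = np.full(N_ROBOTS, -1e6)
    ys = np.full(N_ROBOTS, -1e6)
    ths = np.zeros(N_ROBOTS)
    free = ~pinned
    if pin_pose is not None:
        pin_pose = np.asarray(pin_pose, dtype=float)
        xs[pinned] = pin_pose[pinned, 0]
        ys[pinned] = pin_pose[pinned, 1]
        ths[pinned] = pin_pose[pinned, 2]
    if init_poses is not None:
        init_poses = np.asarray(init_poses, dtype=float)
        sel = free & active
        xs[sel] = init_poses[sel, 0]
        ys[sel] = init_poses[sel, 1]
        ths[sel] = init_poses[sel, 2]
    else:
        _kernels.seed_rng(int(rng.integers(2**31)))
        ok = _kernels.init_poses_kernel(
            xs, ys, ths, free, active, config.side_length,
            config.robot_diameter, config.exclude_zones_at_start,
            config.zones, config.zone_radius, 1000)
        if not ok:
            raise RuntimeError("could not place scripted robots")

    init_pose = np.column_stack([xs, ys, ths])
    pos = np.zeros((steps, N_ROBOTS, 3))
    ctrl = np.zeros((steps, N_ROBOTS, 2))
    zone = np.full((steps, N_ROBOTS), -1, dtype=np.int64)
    collided = np.zeros((steps, N_ROBOTS), dtype=bool)
    n_sense = steps if record_sensors else 0
    retina = np.zeros((n_sense, N_ROBOTS, 15))
    smell = np.zeros((n_sense, N_ROBOTS, 2))
    ground = np.zeros((n_sense, N_ROBOTS))
    fit_col = np.zeros(N_ROBOTS)
    fit_ind = np.zeros(N_ROBOTS)
    out15 = np.empty(15)
    coll_row = np.empty(N_ROBOTS, dtype=bool)

    poses = init_pose.copy()
    for t in range(steps):
        if record_sensors:
            for i in range(N_ROBOTS):
                if not active[i]:
                    continue
                _kernels.retina_kernel(poses[:, 0].copy(), poses[:, 1].copy(),
                                       poses[:, 2].copy(), active, i,
                                       COLOUR_NORM, config.robot_radius, out15)
                retina[t, i] = out15
                smell[t, i] = _kernels.smell_kernel(
                    poses[i, 0], poses[i, 1], poses[i, 2], config.zones)
                ground[t, i] = 1.0 if _kernels.zone_id_kernel(
                    poses[i, 0], poses[i, 1], config.zones,
                    config.zone_radius) >= 0 else 0.0
        for i in range(N_ROBOTS):
            if not active[i] or pinned[i]:
                continue
            vl, vr = policies[i].controls(t, i, poses, config, rng)
            ctrl[t, i] = (vl, vr)
        for i in range(N_ROBOTS):
            if active[i] and not pinned[i]:
                poses[i] = _kernels.step_kinematics_kernel(
                    poses[i, 0], poses[i, 1], poses[i, 2],
                    ctrl[t, i, 0], ctrl[t, i, 1], config.robot_diameter)
        if resolve_collisions:
            _kernels.seed_rng(int(rng.integers(2**31)))
            ok = _kernels.resolve_collisions_kernel(
                poses[:, 0], poses[:, 1], poses[:, 2], pinned, active,
                config.side_length, config.robot_diameter,
                config.collision_displacement, 1000, coll_row)
            if not ok:
                raise RuntimeError("collision resolution failed")
            collided[t] = coll_row & active
        zrow = np.array([_kernels.zone_id_kernel(poses[i, 0], poses[i, 1],
                                                 config.zones,
                                                 config.zone_radius)
                         if active[i] else -1 for i in range(N_ROBOTS)])
        zone[t] = zrow
        fit_ind += (zrow >= 0) & active
        za = zrow[active]
        if za.size and (za >= 0).all() and (za == za[0]).all():
            fit_col += active
        pos[t] = poses

    return TrialLog(config=config, seed=int(seed),
                    team=tuple(p.policy for p in policies),
                    init_pose=init_pose, pos=pos, ctrl=ctrl, zone=zone,
                    collided=collided, retina=retina, smell=smell,
                    ground=ground, fit_collective=fit_col,
                    fit_individual=fit_ind, pinned=pinned, active=active)


class ScriptedTeam:
    """A scripted four-robot team exposing the same trial interface as
    :class:`leadersim.evolution.EvolvedTeam`, so every measure protocol
    runs unchanged on fixtures."""

    def __init__(self, policies, config: ArenaConfig,
                 init_poses: np.ndarray | None = None,
                 resolve_collisions: bool = True, label: str = "scripted"):
        if len(policies) != N_ROBOTS:
            raise ValueError("one policy per robot required")
        self.policies = policies
        self.config = config
        self.init_poses = init_poses
        self.resolve_collisions = resolve_collisions
        self.label = label

    def run(self, seed: int, pinned=None, pin_pose=None, active=None,
            record_sensors: bool = False, steps: int | None = None) -> TrialLog:
        import copy
        policies = copy.deepcopy(self.policies)  # reset any per-trial state
        return run_scripted_trial(policies, self.config, seed,
                                  init_poses=self.init_poses, pinned=pinned,
                                  pin_pose=pin_pose, active=active,
                                  steps=steps, record_sensors=record_sensors,
                                  resolve_collisions=self.resolve_collisions)
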