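"""Named scripted scenarios with declared ground truth.

Each scenario builds a :class:`~leadersim.scripted.ScriptedTeam` whose
behaviour encodes a known leadership structure, so the measurement
battery can be validated without evolution:

* ``passive_leader_group`` — robot 0 drives straight to zone 0 and
  ignores everyone; robots 1-3 follow robot 0.  Ground truth: robot 0
  is the leader (argmin of the barycenter quadruple).
* ``weak_active_group`` — as above but the leader spins on the spot
  for a few steps at regular intervals.
* ``strong_active_group`` — the leader orbits a circle near zone 0
  (high mobility, followers kept in view); followers follow.
* ``leaderless_group`` — four random walkers; low leadership signal.
* ``follower_only`` — robot 0 stationary, robots 1-3 follow it.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scripted import ScriptedController, ScriptedTeam
from .world import ArenaConfig


class UnknownScenarioError(KeyError):
    pass


def _passive(config):
    return [ScriptedController("goto_zone", k=0, stop_radius=3.0)] + [
        ScriptedController("follow_colour", k=0) for _ in range(3)]


@dataclass
class _WeakLeader(ScriptedController):
    """Straight-to-zone leader that occasionally turns on the spot."""

    period: int = 150
    spin_steps: int = 6

    def __init__(self, k=0, period=150, spin_steps=6):
        super().__init__("goto_zone", k=k, stop_radius=3.0)
        self.period = period
        self.spin_steps = spin_steps

    def controls(self, t, i, poses, config, rng):
        if t % self.period < self.spin_steps:
            v = config.wheel_speed_max
            return -v, v
        return super().controls(t, i, poses, config, rng)


def _weak(config):
    return [_WeakLeader(k=0)] + [
        ScriptedController("follow_colour", k=0) for _ in range(3)]


def _strong(config):
    cx, cy = config.zones[0]
    leader = ScriptedController("orbit", center=(cx + 14.0, cy), radius=13.0)
    return [leader] + [ScriptedController("follow_colour", k=0)
                       for _ in range(3)]


def _leaderless(config):
    return [ScriptedController("random_walk") for _ in range(4)]


def _follower_only(config):
    return [ScriptedController("stationary")] + [
        ScriptedController("follow_colour", k=0) for _ in range(3)]


SCENARIOS = {
    "passive_leader_group": _passive,
    "weak_active_group": _weak,
    "strong_active_group": _strong,
    "leaderless_group": _leaderless,
    "follower_only": _follower_only,
}


def make_team(scenario: str, config: ArenaConfig) -> ScriptedTeam:
    """Build the scripted team of a named scenario."""
    try:
        builder = SCENARIOS[scenario]
    except KeyError:
        raise UnknownScenarioError(
            f"unknown scenario {scenario!r}; known: {sorted(SCENARIOS)}")
    return ScriptedTeam(builder(config), config, label=scenario)


def make_fixture(scenario: str, config: ArenaConfig, seed: int,
                 record_sensors: bool = True):
    """One trial log of a named scenario (plus the team that produced it)."""
    team = make_team(scenario, config)
    log = team.run(seed, record_sensors=record_sensors)
    return log, team
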