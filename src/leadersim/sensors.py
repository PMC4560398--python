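"""The robot perceptive system.

Three simulated senses:

* a **linear retina** of five RGB photoreceptors spanning a 90-degree
  field of view ([-45, +45] degrees around the heading), each covering
  an 18-degree sector.  A sector that overlaps the angular extent of at
  least one other robot's chassis carries the normalised colour of the
  nearest such robot; otherwise its RGB triple is zero.  There is no
  distance limit: the retina sees across the whole arena.  Walls and
  food zones are invisible to it.
* three **smell sensors**, one per chassis quadrant, reporting which
  quadrant currently faces the nearest food zone on two binary lines.
* a **ground sensor** at the chassis center reading the floor shade:
  1.0 on a (grey) food zone, 0.0 on the white floor.

All sensors are deterministic functions of the world state; perception
is purely relative (readings are invariant under rigid motions of the
whole scene).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import _kernels
from .world import ArenaConfig, RobotPose, WorldState, COLOUR_NORM, N_ROBOTS


@dataclass(frozen=True)
class RetinaReading:
    """15 values in [0,1]: R0,G0,B0, ..., R4,G4,B4, photoreceptor 0 leftmost."""

    values: np.ndarray

    def active_sectors(self) -> np.ndarray:
        """Boolean (5,) mask of photoreceptors with any nonzero component."""
        return self.values.reshape(5, 3).any(axis=1)


@dataclass(frozen=True)
class SmellCode:
    """Two binary lines encoding the quadrant facing the nearest food zone."""

    s0: float
    s1: float


@dataclass(frozen=True)
class GroundReading:
    """Floor shade under the chassis center: 1.0 on a food zone, else 0.0."""

    value: float


def read_retina(state: WorldState, observer: int, config: ArenaConfig,
                active: np.ndarray | None = None) -> RetinaReading:
    """Linear-retina reading for robot ``observer``.

    A robot at center distance d subtends a bearing interval of
    half-angle arcsin(r/d) around its bearing (r the chassis radius);
    sector k covers [-45 + 18k, -27 + 18k) degrees (the last sector is
    closed on the right).  Occlusion: the nearest overlapping robot
    wins each sector.
    """
    if not 0 <= observer < N_ROBOTS:
        raise IndexError(f"observer index {observer} out of range")
    if active is None:
        active = np.ones(N_ROBOTS, dtype=bool)
    out = np.empty(15)
    _kernels.retina_kernel(
        state.poses[:, 0].copy(), state.poses[:, 1].copy(),
        state.poses[:, 2].copy(), active, observer, COLOUR_NORM,
        config.robot_radius, out)
    return RetinaReading(out)


def read_smell(pose: RobotPose, config: ArenaConfig) -> SmellCode:
    """Quadrant code of the nearest food zone relative to the heading.

    Bearing b (degrees, [0, 360)): b in [0, 90) activates the front-left
    sensor, code (0,1); b in [90, 270) the rear sensor, code (1,0); b in
    [270, 360) the front-right sensor, code (1,1).  The code is never
    (0,0): some quadrant always faces the nearest zone.
    """
    s0, s1 = _kernels.smell_kernel(pose.x, pose.y, pose.heading, config.zones)
    return SmellCode(s0, s1)


def read_ground(pose: RobotPose, config: ArenaConfig) -> GroundReading:
    """1.0 if the chassis center is on a food zone, else 0.0."""
    z = _kernels.zone_id_kernel(pose.x, pose.y, config.zones, config.zone_radius)
    return GroundReading(1.0 if z >= 0 else 0.0)
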