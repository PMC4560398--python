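"""The 2D arena: geometry, robot kinematics, collisions and food zones.

The world is a 110 cm square bounded by walls, with two grey circular
food zones of 22 cm diameter on a white floor.  Four differential-drive
robots (circular chassis, 5.5 cm diameter) move in continuous
coordinates; the frame origin is the bottom-left corner, x to the
right, y up, headings in radians CCW from +x.

Speeds are expressed in cm per time step; the step itself carries no
physical duration.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from . import _kernels
from ._kernels import TWO_PI

COLOUR_NAMES = ("green", "blue", "light_blue", "yellow")
#: fixed RGB triple per colour identity, 0-255
COLOUR_RGB = np.array(
    [[0, 255, 0], [0, 0, 255], [0, 255, 255], [255, 255, 0]], dtype=float
)
#: retina-normalised colours (component / 255)
COLOUR_NORM = COLOUR_RGB / 255.0

N_ROBOTS = 4


class ConfigurationError(RuntimeError):
    """Raised when random placement cannot satisfy the geometric constraints."""


@dataclass(frozen=True)
class ArenaConfig:
    """Geometry and physics constants of the world.

    All lengths in cm, speeds in cm/step.
    """

    side_length: float = 110.0
    zone_diameter: float = 22.0
    zone_centers: tuple = ((27.5, 55.0), (82.5, 55.0))
    robot_diameter: float = 5.5
    steps_per_trial: int = 3000
    wheel_speed_max: float = 1.3
    collision_displacement: float = 5.5
    exclude_zones_at_start: bool = False

    def __post_init__(self):
        if self.side_length <= 0:
            raise ValueError("side_length must be positive")
        if self.robot_diameter >= self.zone_diameter:
            raise ValueError("robot_diameter must be smaller than zone_diameter")
        zc = np.asarray(self.zone_centers, dtype=float)
        if zc.shape != (2, 2):
            raise ValueError("exactly two zone centers required")
        if np.allclose(zc[0], zc[1]):
            raise ValueError("zone centers must be distinct")
        r = self.zone_diameter / 2.0
        if (zc - r < 0).any() or (zc + r > self.side_length).any():
            raise ValueError("zones must lie fully inside the arena")

    @property
    def zone_radius(self) -> float:
        return self.zone_diameter / 2.0

    @property
    def robot_radius(self) -> float:
        return self.robot_diameter / 2.0

    @property
    def zones(self) -> np.ndarray:
        """Zone centers as a (2, 2) float array."""
        return np.asarray(self.zone_centers, dtype=float)

    def to_dict(self) -> dict:
        return {
            "side_length": self.side_length,
            "zone_diameter": self.zone_diameter,
            "zone_centers": [list(map(float, c)) for c in self.zone_centers],
            "robot_diameter": self.robot_diameter,
            "steps_per_trial": self.steps_per_trial,
            "wheel_speed_max": self.wheel_speed_max,
            "collision_displacement": self.collision_displacement,
            "exclude_zones_at_start": self.exclude_zones_at_start,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ArenaConfig":
        d = dict(d)
        if "zone_centers" in d:
            d["zone_centers"] = tuple(tuple(c) for c in d["zone_centers"])
        return cls(**d)


@dataclass(frozen=True)
class RobotPose:
    """Position (cm, arena frame) and heading (radians, [0, 2pi)) of one robot."""

    x: float
    y: float
    heading: float
    colour_id: int = 0

    def __post_init__(self):
        object.__setattr__(self, "heading", _kernels.wrap_2pi(float(self.heading)))

    @property
    def colour_name(self) -> str:
        return COLOUR_NAMES[self.colour_id]

    def as_array(self) -> np.ndarray:
        return np.array([self.x, self.y, self.heading])


@dataclass
class WorldState:
    """Poses of the four robots plus step counter and a seedable RNG."""

    poses: np.ndarray              # (4, 3): x, y, heading; row index = colour id
    step_index: int = 0
    rng: np.random.Generator = field(default_factory=np.random.default_rng)

    def pose(self, i: int) -> RobotPose:
        x, y, th = self.poses[i]
        return RobotPose(x, y, th, colour_id=i)

    def copy(self) -> "WorldState":
        clone = WorldState(self.poses.copy(), self.step_index)
        clone.rng.bit_generator.state = self.rng.bit_generator.state
        return clone


def init_world(config: ArenaConfig, seed: int) -> WorldState:
    """Place the four robots uniformly at random with non-overlapping chassis.

    Deterministic given ``seed``.  Raises :class:`ConfigurationError` if
    rejection sampling cannot find a legal configuration.
    """
    if seed < 0:
        raise ValueError("seed must be a non-negative integer")
    xs = np.full(N_ROBOTS, -1e6)
    ys = np.full(N_ROBOTS, -1e6)
    ths = np.zeros(N_ROBOTS)
    free = np.ones(N_ROBOTS, dtype=bool)
    active = np.ones(N_ROBOTS, dtype=bool)
    rng = np.random.default_rng(seed)
    _kernels.seed_rng(int(rng.integers(2**31)))
    ok = _kernels.init_poses_kernel(
        xs, ys, ths, free, active, config.side_length, config.robot_diameter,
        config.exclude_zones_at_start, config.zones, config.zone_radius, 1000)
    if not ok:
        raise ConfigurationError("could not place robots; arena too small?")
    return WorldState(np.column_stack([xs, ys, ths]), 0, rng)


def step_kinematics(pose: RobotPose, v_left: float, v_right: float,
                    config: ArenaConfig) -> RobotPose:
    """Advance one robot by one step of exact differential-drive motion.

    Linear velocity (v_left+v_right)/2 along the heading, angular
    velocity (v_right-v_left)/robot_diameter; the pose is integrated
    along the resulting circular arc in closed form (not Euler), so pure
    translation and pure rotation are exact.
    """
    x, y, th = _kernels.step_kinematics_kernel(
        pose.x, pose.y, pose.heading, float(v_left), float(v_right),
        config.robot_diameter)
    return RobotPose(x, y, th, pose.colour_id)


def resolve_collisions(state: WorldState, config: ArenaConfig,
                       pinned: np.ndarray | None = None) -> WorldState:
    """Reposition any robot overlapping a wall or another robot.

    A colliding robot is moved by ``collision_displacement`` in a random
    direction to a legal spot and given a uniform random heading;
    non-colliding robots are untouched.  Deterministic given the state's
    RNG.  Returns a new :class:`WorldState`.
    """
    xs = state.poses[:, 0].copy()
    ys = state.poses[:, 1].copy()
    ths = state.poses[:, 2].copy()
    if pinned is None:
        pinned = np.zeros(N_ROBOTS, dtype=bool)
    active = np.ones(N_ROBOTS, dtype=bool)
    collided = np.empty(N_ROBOTS, dtype=bool)
    _kernels.seed_rng(int(state.rng.integers(2**31)))
    ok = _kernels.resolve_collisions_kernel(
        xs, ys, ths, pinned, active, config.side_length,
        config.robot_diameter, config.collision_displacement, 1000, collided)
    if not ok:
        raise ConfigurationError("collision resolution failed; arena too crowded?")
    return WorldState(np.column_stack([xs, ys, ths]), state.step_index, state.rng)


def in_zone(pose: RobotPose, config: ArenaConfig):
    """Food-zone id whose disc contains the robot center, else ``None``.

    Membership is the robot-center-inside-disc convention with a
    half-open boundary (strictly inside the 11 cm radius).
    """
    z = _kernels.zone_id_kernel(pose.x, pose.y, config.zones, config.zone_radius)
    return None if z < 0 else int(z)
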