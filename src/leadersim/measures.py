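"""The post-evolution measurement battery.

All leadership diagnostics derive from the distance between each robot
and the group barycenter (the arithmetic mean of the four positions):

* **Barycenter measure** — pin each robot in turn at the arena center
  ("motionless robot") while the other three move freely; average the
  pinned robot's distance to the 4-robot barycenter over 3000 steps,
  20 trials and the last 20 generations' best teams.  The robot with
  the *minimum* value is the leader: followers aggregate around it.
* **Leadership measure** — the (population) standard deviation of the
  four barycenter values; 0 means no leader/follower asymmetry.
* **Individual fitness measure** — with all robots free, the average
  number of steps each robot spends on any food zone (a "virtual"
  per-robot fitness never used during evolution).
* **Collective fitness indicator** — mean of the per-generation best
  group fitness over the final 20 generations.
* **Capability of followers** — pin the identified leader and count the
  steps each follower needs to come within ``reach_radius`` of it
  (censored at trial length).
* **Mobility of leaders** — distinct 5.5 cm grid cells the leader's
  center visits per trial (20 x 20 grid -> between 1 and 400).
* **Vision of leaders** — steps per trial with at least one active
  retina photoreceptor.
* **Removal test** — re-run the final team with one robot deleted and
  compare collective fitness among the survivors with the intact
  baseline.

Team-level protocols accept any object with the ``run(seed, pinned=...,
active=..., record_sensors=...)`` trial interface (evolved teams and
scripted fixtures alike).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .evolution import EvolvedTeam, ReplicationResult
from .world import ArenaConfig, COLOUR_NAMES, N_ROBOTS

DEFAULT_TRIALS = 20
DEFAULT_LAST_GENERATIONS = 20
#: distance (cm) at which a follower counts as having reached the leader
DEFAULT_REACH_RADIUS = 11.0
#: side (cm) of the mobility grid cell == one robot diameter
MOBILITY_CELL = 5.5


@dataclass
class MeasureSuiteResult:
    """The per-replication measure row."""

    barycenter: np.ndarray          # (4,) cm
    leadership_measure: float
    individual_fitness: np.ndarray  # (4,) steps
    collective_fitness_indicator: float
    capability_of_followers: float  # steps
    mobility_of_leaders: float      # cells
    vision_of_leaders: float        # steps
    leader_id: int

    @property
    def leader_colour(self) -> str:
        return COLOUR_NAMES[self.leader_id]

    def as_row(self) -> dict:
        row = {f"barycenter_{COLOUR_NAMES[i]}": float(self.barycenter[i])
               for i in range(N_ROBOTS)}
        row.update({f"individual_fitness_{COLOUR_NAMES[i]}":
                    float(self.individual_fitness[i]) for i in range(N_ROBOTS)})
        row.update(
            leadership_measure=float(self.leadership_measure),
            collective_fitness_indicator=float(self.collective_fitness_indicator),
            capability_of_followers=float(self.capability_of_followers),
            mobility_of_leaders=float(self.mobility_of_leaders),
            vision_of_leaders=float(self.vision_of_leaders),
            leader=self.leader_colour,
        )
        return row


# ---------------------------------------------------------------------------
# geometric primitives


def barycenter(points: np.ndarray) -> np.ndarray:
    """Arithmetic mean of n >= 1 planar points."""
    points = np.atleast_2d(np.asarray(points, dtype=float))
    if points.size == 0:
        raise ValueError("barycenter of an empty point set")
    return points.mean(axis=0)


def euclidean_distance(p, q) -> float:
    """Plain Euclidean distance between two planar points."""
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    return float(np.hypot(*(p - q)))


def leadership_measure(quadruple: np.ndarray) -> float:
    """Population standard deviation (divisor n) of the barycenter quadruple."""
    quadruple = np.asarray(quadruple, dtype=float)
    if quadruple.shape != (N_ROBOTS,):
        raise ValueError("a quadruple of four values is required")
    return float(np.std(quadruple, ddof=0))


def identify_leader(quadruple: np.ndarray) -> int:
    """Leader = argmin of the barycenter quadruple."""
    return int(np.argmin(np.asarray(quadruple)))


# ---------------------------------------------------------------------------
# team-level protocols (one team = one generation's best four genotypes)


def _pin_pose(config: ArenaConfig) -> np.ndarray:
    c = config.side_length / 2.0
    return np.tile([c, c, 0.0], (N_ROBOTS, 1))


def barycenter_quadruple(team, config: ArenaConfig,
                         rng: np.random.Generator,
                         n_trials: int = DEFAULT_TRIALS,
                         include_pinned: bool = True,
                         steps: int | None = None) -> np.ndarray:
    """Single-team barycenter measure.

    For each robot in turn, pin it at the arena center and average its
    per-step distance to the group barycenter over ``n_trials`` trials.
    ``include_pinned`` keeps the motionless robot in the barycenter
    (n = 4); set False for the 3-free-robot variant.
    """
    values = np.zeros(N_ROBOTS)
    for i in range(N_ROBOTS):
        pinned = np.zeros(N_ROBOTS, dtype=bool)
        pinned[i] = True
        acc = 0.0
        for _ in range(n_trials):
            log = team.run(int(rng.integers(2**31)), pinned=pinned,
                           pin_pose=_pin_pose(config), steps=steps)
            pts = log.pos[:, :, :2]
            if not include_pinned:
                others = [j for j in range(N_ROBOTS) if j != i]
                bary = pts[:, others].mean(axis=1)
            else:
                bary = pts.mean(axis=1)
            d = np.hypot(pts[:, i, 0] - bary[:, 0], pts[:, i, 1] - bary[:, 1])
            acc += d.mean()
        values[i] = acc / n_trials
    return values


def individual_fitness_quadruple(team, config: ArenaConfig,
                                 rng: np.random.Generator,
                                 n_trials: int = DEFAULT_TRIALS,
                                 steps: int | None = None) -> np.ndarray:
    """Per-robot mean steps-on-any-zone with all four robots free."""
    acc = np.zeros(N_ROBOTS)
    for _ in range(n_trials):
        log = team.run(int(rng.integers(2**31)), steps=steps)
        acc += log.fit_individual
    return acc / n_trials


def _last_teams(replication: ReplicationResult,
                last_generations: int) -> list[EvolvedTeam]:
    if replication.n_generations < last_generations:
        raise ValueError(
            f"replication has {replication.n_generations} generations, "
            f"need at least {last_generations}")
    return [EvolvedTeam(replication.best_team(g), replication.arena,
                        label=f"gen{g}")
            for g in range(replication.n_generations - last_generations,
                           replication.n_generations)]


def barycenter_test(replication: ReplicationResult, config: ArenaConfig,
                    rng: np.random.Generator,
                    n_trials: int = DEFAULT_TRIALS,
                    last_generations: int = DEFAULT_LAST_GENERATIONS,
                    include_pinned: bool = True) -> np.ndarray:
    """Barycenter quadruple averaged over the last-N-generation best teams."""
    teams = _last_teams(replication, last_generations)
    quads = [barycenter_quadruple(t, config, rng, n_trials, include_pinned)
             for t in teams]
    return np.mean(quads, axis=0)


def individual_fitness_test(replication: ReplicationResult,
                            config: ArenaConfig, rng: np.random.Generator,
                            n_trials: int = DEFAULT_TRIALS,
                            last_generations: int = DEFAULT_LAST_GENERATIONS
                            ) -> np.ndarray:
    """Individual fitness quadruple averaged over the last-N best teams."""
    teams = _last_teams(replication, last_generations)
    quads = [individual_fitness_quadruple(t, config, rng, n_trials)
             for t in teams]
    return np.mean(quads, axis=0)


def collective_fitness_indicator(replication_or_series,
                                 last_generations: int = DEFAULT_LAST_GENERATIONS
                                 ) -> float:
    """Mean of the per-generation best group fitness over the final N gens."""
    if isinstance(replication_or_series, ReplicationResult):
        series = replication_or_series.group_best
    else:
        series = np.asarray(replication_or_series, dtype=float)
    if series.shape[0] < last_generations:
        raise ValueError("series shorter than the averaging window")
    return float(series[-last_generations:].mean())


def capability_of_followers(team, leader: int, config: ArenaConfig,
                            rng: np.random.Generator,
                            n_trials: int = DEFAULT_TRIALS,
                            reach_radius: float = DEFAULT_REACH_RADIUS,
                            steps: int | None = None) -> float:
    """Mean steps followers need to first come within reach of the pinned leader.

    Followers that never reach the leader contribute the censored value
    ``steps_per_trial``.
    """
    pinned = np.zeros(N_ROBOTS, dtype=bool)
    pinned[leader] = True
    followers = [j for j in range(N_ROBOTS) if j != leader]
    acc = 0.0
    for _ in range(n_trials):
        log = team.run(int(rng.integers(2**31)), pinned=pinned,
                       pin_pose=_pin_pose(config), steps=steps)
        lead_xy = log.pos[:, leader, :2]
        for j in followers:
            d = np.hypot(log.pos[:, j, 0] - lead_xy[:, 0],
                         log.pos[:, j, 1] - lead_xy[:, 1])
            hits = np.nonzero(d <= reach_radius)[0]
            acc += float(hits[0]) if hits.size else float(log.n_steps)
    return acc / (n_trials * len(followers))


def mobility_of_leaders(trial_logs, leader: int,
                        cell: float = MOBILITY_CELL) -> float:
    """Mean distinct grid cells visited by the leader per trial."""
    counts = []
    for log in trial_logs:
        n_cells = int(np.ceil(log.config.side_length / cell))
        ix = np.clip((log.pos[:, leader, 0] // cell).astype(int), 0, n_cells - 1)
        iy = np.clip((log.pos[:, leader, 1] // cell).astype(int), 0, n_cells - 1)
        counts.append(len(set(zip(ix.tolist(), iy.tolist()))))
    return float(np.mean(counts))


def vision_of_leaders(trial_logs, leader: int) -> float:
    """Mean steps per trial with any active photoreceptor on the leader."""
    counts = []
    for log in trial_logs:
        if not log.has_sensors:
            raise ValueError("trial log lacks retina recordings")
        counts.append(int((log.retina[:, leader, :] > 0).any(axis=1).sum()))
    return float(np.mean(counts))


def free_run_logs(team, rng: np.random.Generator,
                  n_trials: int = DEFAULT_TRIALS,
                  record_sensors: bool = True,
                  steps: int | None = None) -> list:
    """Free-running trials of a team (all robots active, none pinned)."""
    return [team.run(int(rng.integers(2**31)), record_sensors=record_sensors,
                     steps=steps)
            for _ in range(n_trials)]


def removal_test(replication: ReplicationResult, removed,
                 config: ArenaConfig, rng: np.random.Generator,
                 n_trials: int = DEFAULT_TRIALS,
                 leader: int | None = None) -> tuple[float, float]:
    """Collective fitness of the final team with a robot deleted vs. intact.

    ``removed`` is a colour name, a robot index, ``"leader"`` (resolved
    via the barycenter measure unless ``leader`` is given), ``None``
    (nothing removed), or a list of up to two of the above.  Returns
    (mean collective fitness among the survivors, intact baseline) over
    paired seeds.
    """
    team = EvolvedTeam(replication.best_team(-1), config)

    def resolve(item):
        nonlocal leader
        if item == "leader":
            if leader is None:
                leader = identify_leader(barycenter_test(
                    replication, config, rng, n_trials=5, last_generations=1))
            return leader
        if isinstance(item, str):
            return COLOUR_NAMES.index(item)
        return int(item)

    if removed is None:
        removed_idx = []
    elif isinstance(removed, (list, tuple)):
        removed_idx = [resolve(x) for x in removed]
    else:
        removed_idx = [resolve(removed)]
    if len(set(removed_idx)) > 2:
        raise ValueError("removing more than 2 robots is unsupported")
    active = np.ones(N_ROBOTS, dtype=bool)
    active[removed_idx] = False
    seeds = rng.integers(2**31, size=n_trials)
    with_removal = np.mean([
        team.run(int(s), active=active).fit_collective[active].mean()
        if active.any() else 0.0 for s in seeds])
    baseline = np.mean([team.run(int(s)).fit_collective.mean()
                        for s in seeds])
    return float(with_removal), float(baseline)


def measure_suite(replication: ReplicationResult, config: ArenaConfig,
                  rng: np.random.Generator,
                  n_trials: int = DEFAULT_TRIALS,
                  last_generations: int = DEFAULT_LAST_GENERATIONS
                  ) -> MeasureSuiteResult:
    """Run the full measurement battery on one evolved replication."""
    quad = barycenter_test(replication, config, rng, n_trials,
                           last_generations)
    leader = identify_leader(quad)
    indiv = individual_fitness_test(replication, config, rng, n_trials,
                                    last_generations)
    cfi = collective_fitness_indicator(replication, last_generations)
    final_team = EvolvedTeam(replication.best_team(-1), config)
    capability = capability_of_followers(final_team, leader, config, rng,
                                         n_trials)
    logs = free_run_logs(final_team, rng, n_trials, record_sensors=True)
    mobility = mobility_of_leaders(logs, leader)
    vision = vision_of_leaders(logs, leader)
    return MeasureSuiteResult(
        barycenter=quad,
        leadership_measure=leadership_measure(quad),
        individual_fitness=indiv,
        collective_fitness_indicator=cfi,
        capability_of_followers=capability,
        mobility_of_leaders=mobility,
        vision_of_leaders=vision,
        leader_id=leader,
    )
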