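"""The Heterogeneous Genetic Algorithm (HGA).

Each of the four robots (colour roles) is served by its own population
of 20 bit-string genotypes, evolved and ranked separately.  Every
generation the populations are cross-combined into 20 team trials via
independent random permutations (so no index quadruple repeats within a
generation and every genotype is evaluated exactly once), each trial
lasts 3000 steps, and fitness rewards collective foraging: +1 per time
step on which all four robots sit inside the *same* food zone
(``collective`` mode, the default).  Two alternative accountings are
available for comparison: ``individual`` (+1 per step a robot is on any
zone) and ``mixed`` (their sum).

Reproduction per population: the 4 highest-ranked genotypes each
produce 5 offspring — one exact copy (elitism) and four copies mutated
by independent per-bit flips at rate 0.02; ties in rank are broken by
lower genotype index so runs are reproducible.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from . import _kernels
from .controller import GENOTYPE_LENGTH, decode_flat, random_genotype
from .io import TrialLog
from .world import ArenaConfig, COLOUR_NORM, N_ROBOTS

FITNESS_MODES = ("collective", "individual", "mixed")


@dataclass(frozen=True)
class GAConfig:
    """Hyperparameters of the heterogeneous genetic algorithm."""

    generations: int = 600
    population_size: int = 20
    trials: int = 20
    mutation_rate: float = 0.02
    parents_count: int = 4
    offspring_per_parent: int = 5
    elitism_count: int = 1          # exact copies among each parent's offspring
    fitness_mode: str = "collective"

    def __post_init__(self):
        if self.fitness_mode not in FITNESS_MODES:
            raise ValueError(f"fitness_mode must be one of {FITNESS_MODES}")
        if self.parents_count * self.offspring_per_parent != self.population_size:
            raise ValueError("parents_count * offspring_per_parent must equal population_size")
        if self.trials != self.population_size:
            raise ValueError("permutation scheduling requires trials == population_size")

    def to_dict(self) -> dict:
        return {
            "generations": self.generations,
            "population_size": self.population_size,
            "trials": self.trials,
            "mutation_rate": self.mutation_rate,
            "parents_count": self.parents_count,
            "offspring_per_parent": self.offspring_per_parent,
            "elitism_count": self.elitism_count,
            "fitness_mode": self.fitness_mode,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "GAConfig":
        return cls(**d)


# ---------------------------------------------------------------------------
# trial execution


def run_trial(team_bits: np.ndarray, config: ArenaConfig, seed: int,
              mode: str = "collective", pinned: np.ndarray | None = None,
              pin_pose: np.ndarray | None = None,
              active: np.ndarray | None = None,
              record_traj: bool = True, record_sensors: bool = False,
              steps: int | None = None,
              team_ids: tuple | None = None) -> tuple[np.ndarray, TrialLog]:
    """Simulate one 3000-step trial of a four-genotype team.

    Returns (per-robot fitness under ``mode``, TrialLog).  ``pinned``
    robots are held motionless at ``pin_pose`` rows (default: arena
    center, heading 0); ``active`` marks robots present in the world
    (the removal test deactivates one).
    """
    team_bits = np.asarray(team_bits, dtype=np.uint8)
    if team_bits.shape != (N_ROBOTS, GENOTYPE_LENGTH):
        raise ValueError(f"team must be 4 genotypes of {GENOTYPE_LENGTH} bits")
    params = np.stack([decode_flat(g) for g in team_bits])
    return run_trial_params(params, config, seed, mode=mode, pinned=pinned,
                            pin_pose=pin_pose, active=active,
                            record_traj=record_traj,
                            record_sensors=record_sensors, steps=steps,
                            team_ids=team_ids)


def run_trial_params(params: np.ndarray, config: ArenaConfig, seed: int,
                     mode: str = "collective",
                     pinned: np.ndarray | None = None,
                     pin_pose: np.ndarray | None = None,
                     active: np.ndarray | None = None,
                     record_traj: bool = True, record_sensors: bool = False,
                     steps: int | None = None,
                     team_ids: tuple | None = None) -> tuple[np.ndarray, TrialLog]:
    """As :func:`run_trial` but taking decoded (4, 86) parameter rows."""
    if mode not in FITNESS_MODES:
        raise ValueError(f"unknown fitness mode {mode!r}")
    if pinned is None:
        pinned = np.zeros(N_ROBOTS, dtype=bool)
    if active is None:
        active = np.ones(N_ROBOTS, dtype=bool)
    pinned = np.asarray(pinned, dtype=bool)
    active = np.asarray(active, dtype=bool)
    if pin_pose is None:
        c = config.side_length / 2.0
        pin_pose = np.tile([c, c, 0.0], (N_ROBOTS, 1))
    pin_pose = np.asarray(pin_pose, dtype=float)
    if steps is None:
        steps = config.steps_per_trial
    out = _kernels.run_trial_kernel(
        np.ascontiguousarray(params, dtype=float), pinned, active,
        pin_pose[:, 0].copy(), pin_pose[:, 1].copy(), pin_pose[:, 2].copy(),
        steps, config.side_length, config.robot_diameter, config.zones,
        config.zone_radius, config.wheel_speed_max,
        config.collision_displacement, config.exclude_zones_at_start,
        COLOUR_NORM, int(seed), record_traj, record_sensors)
    (init_pose, pos, ctrl, zone, collided, retina, smell, ground,
     fit_col, fit_ind) = out
    log = TrialLog(config=config, seed=int(seed),
                   team=tuple(team_ids) if team_ids else tuple(range(N_ROBOTS)),
                   init_pose=init_pose, pos=pos, ctrl=ctrl, zone=zone,
                   collided=collided, retina=retina, smell=smell,
                   ground=ground, fit_collective=fit_col,
                   fit_individual=fit_ind, pinned=pinned, active=active)
    return log.fitness(mode), log


def score_zone_log(zone: np.ndarray, mode: str = "collective",
                   active: np.ndarray | None = None) -> np.ndarray:
    """Fitness accounting applied to a (T, 4) zone-occupancy log.

    collective: every robot gains +1 on each step where all active
    robots occupy the same zone; individual: +1 per step a robot is on
    any zone; mixed: their sum.
    """
    if mode not in FITNESS_MODES:
        raise ValueError(f"unknown fitness mode {mode!r}")
    zone = np.asarray(zone)
    if active is None:
        active = np.ones(zone.shape[1], dtype=bool)
    za = zone[:, active]
    ind = (zone >= 0).sum(axis=0).astype(float)
    ind[~active] = 0.0
    same = (za >= 0).all(axis=1) & (za == za[:, :1]).all(axis=1)
    col = np.where(active, float(same.sum()), 0.0)
    if mode == "collective":
        return col
    if mode == "individual":
        return ind
    return col + ind


# ---------------------------------------------------------------------------
# scheduling, selection, reproduction


def sample_schedule(rng: np.random.Generator, population_size: int = 20,
                    n_populations: int = N_ROBOTS) -> np.ndarray:
    """One independent uniform permutation per population.

    Returns (n_populations, population_size); trial t is played by the
    quadruple schedule[:, t].  Permutation scheduling guarantees both
    that no quadruple repeats within a generation and that every
    genotype is evaluated exactly once.
    """
    return np.stack([rng.permutation(population_size)
                     for _ in range(n_populations)])


def rank_and_reproduce(genotypes: np.ndarray, fitness: np.ndarray,
                       rng: np.random.Generator,
                       ga: GAConfig = GAConfig()) -> np.ndarray:
    """Truncation selection with elitism and per-bit mutation.

    The top ``parents_count`` genotypes (descending fitness, ties broken
    by lower index) each produce ``offspring_per_parent`` offspring: the
    first ``elitism_count`` are exact copies, the rest have every bit
    flipped independently with probability ``mutation_rate``.
    """
    genotypes = np.asarray(genotypes, dtype=np.uint8)
    fitness = np.asarray(fitness, dtype=float)
    if fitness.shape[0] != genotypes.shape[0]:
        raise ValueError("one fitness per genotype required")
    order = np.argsort(-fitness, kind="stable")
    children = []
    for p in order[:ga.parents_count]:
        parent = genotypes[p]
        for k in range(ga.offspring_per_parent):
            if k < ga.elitism_count:
                children.append(parent.copy())
            else:
                flips = rng.random(parent.shape[0]) < ga.mutation_rate
                children.append(parent ^ flips.astype(np.uint8))
    return np.stack(children)


# ---------------------------------------------------------------------------
# replication driver


@dataclass
class ReplicationResult:
    """One evolutionary replication: fitness history plus genotype archives."""

    seed: int
    arena: ArenaConfig
    ga: GAConfig
    fitness: np.ndarray           # (G, 4, population_size)
    group_best: np.ndarray        # (G,) best trial collective score per generation
    group_mean: np.ndarray        # (G,) mean over the 20 trials
    best_teams: np.ndarray        # (G, 4, 688) top-ranked genotype per population
    final_populations: np.ndarray  # (4, population_size, 688)

    @property
    def n_generations(self) -> int:
        return self.fitness.shape[0]

    def best_team(self, generation: int = -1) -> np.ndarray:
        """Top-ranked genotype of each population at a generation, (4, 688)."""
        return self.best_teams[generation]


def _gen_rng(stream_key: int, generation: int) -> np.random.Generator:
    # per-generation substream so checkpoints need no RNG state capture
    return np.random.default_rng([stream_key, generation])


def run_replication(arena: ArenaConfig, ga: GAConfig, seed: int,
                    progress: bool = False,
                    initial_populations: np.ndarray | None = None,
                    start_generation: int = 0,
                    history: dict | None = None) -> ReplicationResult:
    """Run one full evolutionary replication, reproducible from ``seed``.

    All randomness derives from named substreams of the master seed
    (population init / schedule / mutation / trials), each substream
    keyed additionally by generation, so a run can be resumed from a
    checkpoint by passing ``initial_populations`` + ``start_generation``
    + the accumulated ``history`` (as produced by
    :func:`leadersim.harness.load_checkpoint`).
    """
    ss = np.random.SeedSequence(seed)
    s_pop, s_sched, s_mut, s_trial = (int(x) for x in ss.generate_state(4))

    P = ga.population_size
    G = ga.generations
    if initial_populations is None:
        rng_pop = np.random.default_rng(s_pop)
        pops = np.stack([
            np.stack([random_genotype(rng_pop) for _ in range(P)])
            for _ in range(N_ROBOTS)])
    else:
        pops = np.asarray(initial_populations, dtype=np.uint8).copy()

    fitness = np.zeros((G, N_ROBOTS, P))
    group_best = np.zeros(G)
    group_mean = np.zeros(G)
    best_teams = np.zeros((G, N_ROBOTS, GENOTYPE_LENGTH), dtype=np.uint8)
    if history is not None:
        g0 = start_generation
        fitness[:g0] = history["fitness"]
        group_best[:g0] = history["group_best"]
        group_mean[:g0] = history["group_mean"]
        best_teams[:g0] = history["best_teams"]

    for g in range(start_generation, G):
        params = _decode_populations(pops)
        schedule = sample_schedule(_gen_rng(s_sched, g), P)
        trial_seeds = _gen_rng(s_trial, g).integers(2**31, size=ga.trials)
        gen_fit = np.zeros((N_ROBOTS, P))
        trial_collective = np.zeros(ga.trials)
        for t in range(ga.trials):
            team_params = params[np.arange(N_ROBOTS), schedule[:, t]]
            fit, log = run_trial_params(team_params, arena,
                                        int(trial_seeds[t]),
                                        mode=ga.fitness_mode,
                                        record_traj=False)
            gen_fit[np.arange(N_ROBOTS), schedule[:, t]] = fit
            trial_collective[t] = log.fit_collective[0]
        fitness[g] = gen_fit
        group_best[g] = trial_collective.max()
        group_mean[g] = trial_collective.mean()
        rng_mut = _gen_rng(s_mut, g)
        for p in range(N_ROBOTS):
            champion = int(np.argsort(-gen_fit[p], kind="stable")[0])
            best_teams[g, p] = pops[p, champion]
            pops[p] = rank_and_reproduce(pops[p], gen_fit[p], rng_mut, ga)
        if progress and (g % 10 == 0 or g == G - 1):
            print(f"generation {g:4d}  group best {group_best[g]:7.1f}  "
                  f"mean {group_mean[g]:7.1f}")

    return ReplicationResult(seed=seed, arena=arena, ga=ga, fitness=fitness,
                             group_best=group_best, group_mean=group_mean,
                             best_teams=best_teams, final_populations=pops)


def _decode_populations(pops: np.ndarray) -> np.ndarray:
    """(4, P, 688) bits -> (4, P, 86) decoded parameters."""
    n_pop, P, L = pops.shape
    flat = pops.reshape(n_pop * P, L)
    return np.stack([decode_flat(g) for g in flat]).reshape(n_pop, P, -1)


class EvolvedTeam:
    """A four-genotype team, runnable under the measure protocols."""

    def __init__(self, genotypes: np.ndarray, config: ArenaConfig,
                 label: str = "evolved"):
        self.genotypes = np.asarray(genotypes, dtype=np.uint8)
        if self.genotypes.shape != (N_ROBOTS, GENOTYPE_LENGTH):
            raise ValueError("team must be 4 genotypes of 688 bits")
        self.config = config
        self.label = label
        self._params = np.stack([decode_flat(g) for g in self.genotypes])

    def run(self, seed: int, pinned: np.ndarray | None = None,
            pin_pose: np.ndarray | None = None,
            active: np.ndarray | None = None,
            record_sensors: bool = False, steps: int | None = None) -> TrialLog:
        _, log = run_trial_params(self._params, self.config, seed,
                                  pinned=pinned, pin_pose=pin_pose,
                                  active=active, record_traj=True,
                                  record_sensors=record_sensors, steps=steps,
                                  team_ids=(self.label,) * N_ROBOTS)
        return log
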