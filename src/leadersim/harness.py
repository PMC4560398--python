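"""Run management: replication archives, checkpoints, measure tables, reports.

A run directory holds one subdirectory per replication (``rep00``,
``rep01``, ...), each containing a YAML manifest, per-genotype fitness
and group-fitness CSV tables, and hex-text genotype archives (the
per-generation best team of every population plus the final
populations).  All artifacts round-trip byte-identically.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .controller import GENOTYPE_LENGTH
from .evolution import GAConfig, ReplicationResult, run_replication
from .io import (FORMAT_VERSION, PARAMETER_ORDER, genotype_to_hex,
                 hex_to_genotype, read_genotype_table, write_genotype_table)
from .measures import MeasureSuiteResult
from .temporal import classify_style, pearson
from .world import ArenaConfig, N_ROBOTS

#: the three correlation pairs of the analysis report
CORRELATION_PAIRS = (
    ("leadership_measure", "collective_fitness_indicator"),
    ("capability_of_followers", "mobility_of_leaders"),
    ("mobility_of_leaders", "vision_of_leaders"),
)


# ---------------------------------------------------------------------------
# replication archives


def save_replication(rep: ReplicationResult, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    manifest = {
        "format_version": FORMAT_VERSION,
        "parameter_order": PARAMETER_ORDER,
        "seed": int(rep.seed),
        "arena": rep.arena.to_dict(),
        "ga": rep.ga.to_dict(),
        "generations": int(rep.n_generations),
    }
    with (directory / "manifest.yaml").open("w") as fh:
        yaml.safe_dump(manifest, fh, sort_keys=True)

    G, _, P = rep.fitness.shape
    gen, pop, idx = np.meshgrid(np.arange(G), np.arange(N_ROBOTS),
                                np.arange(P), indexing="ij")
    pd.DataFrame({
        "generation": gen.ravel(), "population": pop.ravel(),
        "index": idx.ravel(), "fitness": rep.fitness.ravel(),
    }).to_csv(directory / "fitness.csv", index=False, float_format="%.12g")
    pd.DataFrame({
        "generation": np.arange(G),
        "group_best": rep.group_best,
        "group_mean": rep.group_mean,
    }).to_csv(directory / "group_fitness.csv", index=False,
              float_format="%.12g")
    write_genotype_table(
        directory / "best_teams.txt",
        ((g, p, 0, rep.best_teams[g, p])
         for g in range(G) for p in range(N_ROBOTS)))
    write_genotype_table(
        directory / "final_populations.txt",
        ((G - 1, p, i, rep.final_populations[p, i])
         for p in range(N_ROBOTS) for i in range(P)))


def load_replication(directory) -> ReplicationResult:
    directory = Path(directory)
    with (directory / "manifest.yaml").open() as fh:
        manifest = yaml.safe_load(fh)
    arena = ArenaConfig.from_dict(manifest["arena"])
    ga = GAConfig.from_dict(manifest["ga"])
    G = manifest["generations"]
    P = ga.population_size

    fit_df = pd.read_csv(directory / "fitness.csv")
    fitness = np.zeros((G, N_ROBOTS, P))
    fitness[fit_df["generation"], fit_df["population"], fit_df["index"]] = \
        fit_df["fitness"]
    grp = pd.read_csv(directory / "group_fitness.csv")
    best_teams = np.zeros((G, N_ROBOTS, GENOTYPE_LENGTH), dtype=np.uint8)
    for g, p, _i, bits in read_genotype_table(directory / "best_teams.txt"):
        best_teams[g, p] = bits
    final_pops = np.zeros((N_ROBOTS, P, GENOTYPE_LENGTH), dtype=np.uint8)
    for _g, p, i, bits in read_genotype_table(
            directory / "final_populations.txt"):
        final_pops[p, i] = bits
    return ReplicationResult(
        seed=manifest["seed"], arena=arena, ga=ga, fitness=fitness,
        group_best=grp["group_best"].to_numpy(),
        group_mean=grp["group_mean"].to_numpy(),
        best_teams=best_teams, final_populations=final_pops)


# ---------------------------------------------------------------------------
# checkpoint / resume


def _checkpoint_path(directory) -> Path:
    return Path(directory) / "checkpoint.yaml"


def save_checkpoint(directory, generation: int, rep: ReplicationResult) -> None:
    """Persist progress through ``generation`` (exclusive upper bound)."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    payload = {
        "format_version": FORMAT_VERSION,
        "generation": int(generation),
        "seed": int(rep.seed),
        "arena": rep.arena.to_dict(),
        "ga": rep.ga.to_dict(),
        "populations": [[genotype_to_hex(rep.final_populations[p, i])
                         for i in range(rep.ga.population_size)]
                        for p in range(N_ROBOTS)],
        "group_best": rep.group_best[:generation].tolist(),
        "group_mean": rep.group_mean[:generation].tolist(),
        "fitness": rep.fitness[:generation].tolist(),
        "best_teams": [[genotype_to_hex(rep.best_teams[g, p])
                        for p in range(N_ROBOTS)]
                       for g in range(generation)],
    }
    with _checkpoint_path(directory).open("w") as fh:
        yaml.safe_dump(payload, fh, sort_keys=True)


def load_checkpoint(directory):
    """Return (start_generation, populations, history) or None."""
    path = _checkpoint_path(directory)
    if not path.exists():
        return None
    with path.open() as fh:
        payload = yaml.safe_load(fh)
    g0 = payload["generation"]
    pops = np.stack([
        np.stack([hex_to_genotype(h) for h in row])
        for row in payload["populations"]])
    history = {
        "fitness": np.asarray(payload["fitness"], dtype=float),
        "group_best": np.asarray(payload["group_best"], dtype=float),
        "group_mean": np.asarray(payload["group_mean"], dtype=float),
        "best_teams": np.stack([
            np.stack([hex_to_genotype(h) for h in row])
            for row in payload["best_teams"]]) if g0 else
        np.zeros((0, N_ROBOTS, GENOTYPE_LENGTH), dtype=np.uint8),
    }
    return g0, pops, history


def run_replication_archived(arena: ArenaConfig, ga: GAConfig, seed: int,
                             directory, checkpoint_every: int = 100,
                             progress: bool = False) -> ReplicationResult:
    """Run (or resume) a replication, checkpointing every N generations.

    Because every RNG substream is keyed by (master seed, generation),
    a resumed run is bit-identical to an uninterrupted one.
    """
    directory = Path(directory)
    ck = load_checkpoint(directory)
    if ck is not None:
        start, pops, history = ck
    else:
        start, pops, history = 0, None, None
    rep = None
    g = start
    while g < ga.generations:
        target = min(g + checkpoint_every, ga.generations)
        chunk_ga = dataclasses.replace(ga, generations=target)
        rep = run_replication(arena, chunk_ga, seed, progress=progress,
                              initial_populations=pops, start_generation=g,
                              history=history)
        g = target
        pops = rep.final_populations
        history = {"fitness": rep.fitness, "group_best": rep.group_best,
                   "group_mean": rep.group_mean, "best_teams": rep.best_teams}
        if g < ga.generations:
            save_checkpoint(directory, g, rep)
    rep = dataclasses.replace(rep, ga=ga)
    save_replication(rep, directory)
    path = _checkpoint_path(directory)
    if path.exists():
        path.unlink()
    return rep


# ---------------------------------------------------------------------------
# measure tables and the analysis report


def measures_to_frame(results: dict) -> pd.DataFrame:
    """{replication id: MeasureSuiteResult} -> one tabular row each."""
    rows = []
    for rep_id, res in results.items():
        row = {"replication": rep_id}
        row.update(res.as_row())
        rows.append(row)
    return pd.DataFrame(rows)


def correlation_report(measures: pd.DataFrame) -> pd.DataFrame:
    """The three (rho, p, n) correlation blocks of the analysis."""
    rows = []
    for xcol, ycol in CORRELATION_PAIRS:
        rho, p = pearson(measures[xcol], measures[ycol])
        rows.append({"x": xcol, "y": ycol, "rho": rho, "p_value": p,
                     "n": len(measures)})
    return pd.DataFrame(rows)


def style_report(measures: pd.DataFrame) -> pd.DataFrame:
    cls = classify_style(measures["vision_of_leaders"].to_numpy(),
                         measures["mobility_of_leaders"].to_numpy())
    out = measures[["replication", "vision_of_leaders",
                    "mobility_of_leaders", "leader"]].copy()
    out["style"] = cls.labels
    return out


def render_report(measures: pd.DataFrame) -> str:
    """Human-readable analysis report: measure rows, styles, correlations."""
    lines = ["# leadersim analysis report", "",
             f"replications: {len(measures)}", "", "## measures", ""]
    lines.append(measures.to_string(index=False))
    lines += ["", "## leadership styles", ""]
    lines.append(style_report(measures).to_string(index=False))
    lines += ["", "## correlations", ""]
    lines.append(correlation_report(measures).to_string(index=False))
    styles = style_report(measures)["style"]
    frac = styles.value_counts(normalize=True)
    lines += ["", "## style distribution", ""]
    for name, f in frac.items():
        lines.append(f"{name}: {100 * f:.0f}%")
    return "\n".join(lines) + "\n"
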