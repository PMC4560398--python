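"""File formats and containers: trial logs, genotype archives, run configs.

Everything is plain text so artifacts are diffable and language
neutral: trial logs are CSV tables with a JSON metadata header line,
genotype archives are hex-text (172 hex characters per 688-bit
genotype) with a YAML manifest, configurations are YAML.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import _kernels
from .world import ArenaConfig, N_ROBOTS
from .controller import GENOTYPE_LENGTH

FORMAT_VERSION = 1
#: frozen genotype parameter ordering, recorded in every manifest
PARAMETER_ORDER = (
    "input_hidden[18x4] row-major by input, hidden_bias[4], "
    "hidden_output[4x2] row-major by hidden, output_bias[2]; "
    "8 bits per parameter, MSB first, byte b -> -5 + 10*b/255"
)


def config_hash(config: ArenaConfig) -> str:
    """Short stable hash of an arena configuration."""
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


# ---------------------------------------------------------------------------
# trial logs


@dataclass
class TrialLog:
    """Full record of one trial.

    Pose rows are post-movement (after collision resolution); sensor
    readings and wheel commands at step t are the ones computed from the
    step-t pre-movement state, i.e. the inputs/outputs that produced the
    step-t pose.  ``retina``/``smell``/``ground`` may be empty when the
    trial was run without sensor recording.
    """

    config: ArenaConfig
    seed: int
    team: tuple                 # identifiers of the four controllers
    init_pose: np.ndarray       # (4, 3)
    pos: np.ndarray             # (T, 4, 3)
    ctrl: np.ndarray            # (T, 4, 2)
    zone: np.ndarray            # (T, 4) int, -1 = none
    collided: np.ndarray        # (T, 4) bool
    retina: np.ndarray          # (T, 4, 15) or empty
    smell: np.ndarray           # (T, 4, 2) or empty
    ground: np.ndarray          # (T, 4) or empty
    fit_collective: np.ndarray  # (4,)
    fit_individual: np.ndarray  # (4,)
    pinned: np.ndarray = field(default_factory=lambda: np.zeros(N_ROBOTS, bool))
    active: np.ndarray = field(default_factory=lambda: np.ones(N_ROBOTS, bool))

    @property
    def n_steps(self) -> int:
        return self.pos.shape[0]

    @property
    def has_sensors(self) -> bool:
        return self.retina.shape[0] > 0

    def fitness(self, mode: str = "collective") -> np.ndarray:
        """Per-robot trial fitness under the given accounting mode."""
        if mode == "collective":
            return self.fit_collective.copy()
        if mode == "individual":
            return self.fit_individual.copy()
        if mode == "mixed":
            return self.fit_collective + self.fit_individual
        raise ValueError(f"unknown fitness mode {mode!r}")

    # -- replay -------------------------------------------------------------

    def replay_ok(self, atol: float = 1e-9) -> bool:
        """Check that logged controls reproduce logged poses.

        Re-applies the closed-form kinematics to each robot's previous
        pose and compares with the logged pose, skipping steps where the
        robot was repositioned by collision handling (those moves are
        random displacements, not kinematics).
        """
        diam = self.config.robot_diameter
        for i in range(N_ROBOTS):
            if not self.active[i] or self.pinned[i]:
                continue
            prev = self.init_pose[i]
            for t in range(self.n_steps):
                if not self.collided[t, i]:
                    x, y, th = _kernels.step_kinematics_kernel(
                        prev[0], prev[1], prev[2],
                        self.ctrl[t, i, 0], self.ctrl[t, i, 1], diam)
                    if (abs(x - self.pos[t, i, 0]) > atol
                            or abs(y - self.pos[t, i, 1]) > atol
                            or abs(th - self.pos[t, i, 2]) > atol):
                        return False
                prev = self.pos[t, i]
        return True

    # -- tabular export -----------------------------------------------------

    def to_frame(self) -> pd.DataFrame:
        """Long-format table, one row per (step, robot)."""
        T = self.n_steps
        idx = np.arange(T)
        cols = {
            "step": np.repeat(idx, N_ROBOTS),
            "robot": np.tile(np.arange(N_ROBOTS), T),
            "x": self.pos[:, :, 0].ravel(),
            "y": self.pos[:, :, 1].ravel(),
            "heading": self.pos[:, :, 2].ravel(),
            "v_left": self.ctrl[:, :, 0].ravel(),
            "v_right": self.ctrl[:, :, 1].ravel(),
            "zone": self.zone.ravel(),
            "collided": self.collided.ravel().astype(int),
        }
        if self.has_sensors:
            cols["s0"] = self.smell[:, :, 0].ravel()
            cols["s1"] = self.smell[:, :, 1].ravel()
            cols["ground"] = self.ground.ravel()
            for k in range(15):
                cols[f"r{k}"] = self.retina[:, :, k].ravel()
        return pd.DataFrame(cols)

    def to_csv(self, path) -> None:
        meta = {
            "format_version": FORMAT_VERSION,
            "config": self.config.to_dict(),
            "config_hash": config_hash(self.config),
            "seed": int(self.seed),
            "team": list(self.team),
            "pinned": self.pinned.astype(int).tolist(),
            "active": self.active.astype(int).tolist(),
            "init_pose": self.init_pose.tolist(),
            "fit_collective": self.fit_collective.tolist(),
            "fit_individual": self.fit_individual.tolist(),
        }
        path = Path(path)
        with path.open("w") as fh:
            fh.write("# " + json.dumps(meta, sort_keys=True) + "\n")
            self.to_frame().to_csv(fh, index=False, float_format="%.12g")

    @classmethod
    def from_csv(cls, path) -> "TrialLog":
        path = Path(path)
        with path.open() as fh:
            header = fh.readline()
            if not header.startswith("# "):
                raise ValueError(f"{path}: missing metadata header")
            meta = json.loads(header[2:])
            df = pd.read_csv(fh)
        T = df["step"].nunique()
        shape = (T, N_ROBOTS)
        has_sensors = "r0" in df.columns

        def grid(col):
            return df[col].to_numpy().reshape(shape)

        pos = np.stack([grid("x"), grid("y"), grid("heading")], axis=-1)
        ctrl = np.stack([grid("v_left"), grid("v_right")], axis=-1)
        if has_sensors:
            retina = np.stack([grid(f"r{k}") for k in range(15)], axis=-1)
            smell = np.stack([grid("s0"), grid("s1")], axis=-1)
            ground = grid("ground")
        else:
            retina = np.zeros((0, N_ROBOTS, 15))
            smell = np.zeros((0, N_ROBOTS, 2))
            ground = np.zeros((0, N_ROBOTS))
        return cls(
            config=ArenaConfig.from_dict(meta["config"]),
            seed=meta["seed"],
            team=tuple(meta["team"]),
            init_pose=np.asarray(meta["init_pose"], dtype=float),
            pos=pos,
            ctrl=ctrl,
            zone=grid("zone").astype(np.int64),
            collided=grid("collided").astype(bool),
            retina=retina,
            smell=smell,
            ground=ground,
            fit_collective=np.asarray(meta["fit_collective"], dtype=float),
            fit_individual=np.asarray(meta["fit_individual"], dtype=float),
            pinned=np.asarray(meta["pinned"], dtype=bool),
            active=np.asarray(meta["active"], dtype=bool),
        )


# ---------------------------------------------------------------------------
# genotype hex text


def genotype_to_hex(bits: np.ndarray) -> str:
    bits = np.asarray(bits, dtype=np.uint8)
    if bits.shape != (GENOTYPE_LENGTH,):
        raise ValueError("genotype must have 688 bits")
    return np.packbits(bits).tobytes().hex()


def hex_to_genotype(text: str) -> np.ndarray:
    raw = bytes.fromhex(text.strip())
    if len(raw) * 8 != GENOTYPE_LENGTH:
        raise ValueError("hex string does not encode 688 bits")
    return np.unpackbits(np.frombuffer(raw, dtype=np.uint8))


def write_genotype_table(path, rows) -> None:
    """Write (generation, population, index, hex) rows as whitespace table."""
    with Path(path).open("w") as fh:
        fh.write("generation population index genotype_hex\n")
        for gen, pop, idx, bits in rows:
            fh.write(f"{gen} {pop} {idx} {genotype_to_hex(bits)}\n")


def read_genotype_table(path):
    """Yield (generation, population, index, bits) from a genotype table."""
    with Path(path).open() as fh:
        header = fh.readline()
        for line in fh:
            gen, pop, idx, hx = line.split()
            yield int(gen), int(pop), int(idx), hex_to_genotype(hx)


# ---------------------------------------------------------------------------
# run configuration files


def load_config(path):
    """Load (ArenaConfig, dict-of-GA-keys) from a YAML run configuration."""
    with Path(path).open() as fh:
        raw = yaml.safe_load(fh) or {}
    arena = ArenaConfig.from_dict(raw.get("arena", {}))
    ga = raw.get("ga", {})
    return arena, ga


def save_config(path, arena: ArenaConfig, ga: dict) -> None:
    with Path(path).open("w") as fh:
        yaml.safe_dump({"arena": arena.to_dict(), "ga": dict(ga)}, fh,
                       sort_keys=True)
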