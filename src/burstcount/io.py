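"""Persistence: trial tables (CSV), epochs and maps (HDF5), results (JSON),
run configuration (YAML), and deterministic seed derivation.

Every file carries a schema tag so stale or foreign artifacts fail loudly
instead of half-parsing.
"""

from __future__ import annotations

import hashlib
import json
import zlib
from dataclasses import asdict, dataclass, field
from pathlib import Path

import h5py
import numpy as np
import pandas as pd
import yaml

from .containers import EpochArray
from .design import SCHEDULE_COLUMNS
from .simulate import GroundTruth

TRIALS_SCHEMA = "burstcount/trials/v1"
EPOCHS_SCHEMA = "burstcount/epochs/v1"
RESULTS_SCHEMA = "burstcount/results/v1"
CONFIG_SCHEMA = "burstcount/config/v1"


class SchemaError(RuntimeError):
    """Raised when an artifact's schema tag is missing or wrong."""


def derive_seed(master_seed: int, label: str) -> int:
    """Deterministic per-stage seed below 2**31."""
    ss = np.random.SeedSequence([int(master_seed), zlib.crc32(label.encode())])
    return int(ss.generate_state(1)[0] % (2 ** 31))


# ---------------------------------------------------------------------------
# Trial tables

def write_trials(schedule: pd.DataFrame, path: str | Path) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# {TRIALS_SCHEMA}\n")
        schedule.to_csv(fh, index=False)


def read_trials(path: str | Path) -> pd.DataFrame:
    path = Path(path)
    with open(path) as fh:
        header = fh.readline().strip()
        if header != f"# {TRIALS_SCHEMA}":
            raise SchemaError(f"{path}: expected trial-table schema "
                              f"{TRIALS_SCHEMA!r}, found {header!r}")
        df = pd.read_csv(fh)
    missing = set(SCHEDULE_COLUMNS) - set(df.columns)
    if missing:
        raise SchemaError(f"{path}: missing columns {sorted(missing)}")
    df["response"] = df["response"].astype("Int64")
    df["correct"] = df["correct"].astype(bool)
    df["rejected"] = df["rejected"].astype(bool)
    return df


# ---------------------------------------------------------------------------
# Epoch containers

def write_epochs(epochs: dict[int, EpochArray], path: str | Path,
                 seed: int | None = None) -> None:
    with h5py.File(path, "w") as h5:
        h5.attrs["schema"] = EPOCHS_SCHEMA
        if seed is not None:
            h5.attrs["seed"] = int(seed)
        for p, ep in epochs.items():
            g = h5.create_group(f"participant_{p}")
            g.create_dataset("data", data=ep.data, chunks=True,
                             compression="gzip", compression_opts=1)
            g.attrs["fs"] = ep.fs
            g.attrs["t_start"] = ep.t_start
            g.attrs["audio_offset"] = ep.audio_offset


def read_epochs(path: str | Path) -> dict[int, EpochArray]:
    with h5py.File(path, "r") as h5:
        if h5.attrs.get("schema") != EPOCHS_SCHEMA:
            raise SchemaError(f"{path}: not a {EPOCHS_SCHEMA} container")
        out = {}
        for name, g in h5.items():
            p = int(name.rsplit("_", 1)[1])
            out[p] = EpochArray(g["data"][()], fs=float(g.attrs["fs"]),
                                t_start=float(g.attrs["t_start"]),
                                audio_offset=float(g.attrs["audio_offset"]))
    return out


# ---------------------------------------------------------------------------
# Results and configuration

def _jsonable(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON-serialisable: {type(obj)}")


def write_result(result: dict, path: str | Path, config_hash: str | None = None) -> None:
    payload = {"schema": RESULTS_SCHEMA, "config_hash": config_hash, **result}
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True,
                                     default=_jsonable) + "\n")


def read_result(path: str | Path) -> dict:
    payload = json.loads(Path(path).read_text())
    if payload.get("schema") != RESULTS_SCHEMA:
        raise SchemaError(f"{path}: not a {RESULTS_SCHEMA} document")
    return payload


@dataclass
class RunConfig:
    """Everything needed to regenerate and analyse one synthetic study."""

    master_seed: int = 1
    n_participants: int = 20
    n_blocks: int = 4
    base_reps: int = 8
    high_prev_reps: int = 32
    truth: GroundTruth = field(default_factory=GroundTruth)
    # spectral settings
    freq_lo: float = 3.0
    freq_hi: float = 100.0
    bandwidth: float = 6.0
    filter_order: int = 3
    map_decimate: int = 12
    profile_decimate: int = 4
    # stage settings
    n_permutations: int = 5000
    alpha_inclusion: float = 0.05
    connectivity: int = 8
    chauvenet_criterion: float = 0.5
    output_dir: str = "scratch/run"

    def stage_seed(self, stage: str) -> int:
        return derive_seed(self.master_seed, stage)

    def to_dict(self) -> dict:
        d = asdict(self)
        d["truth"] = self.truth.to_dict()
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        d.pop("schema", None)
        if "truth" in d:
            d["truth"] = GroundTruth.from_dict(d["truth"])
        return cls(**d)

    def config_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True, default=_jsonable)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


def write_config(config: RunConfig, path: str | Path) -> None:
    doc = {"schema": CONFIG_SCHEMA, **config.to_dict()}
    Path(path).write_text(yaml.safe_dump(doc, sort_keys=True))


def read_config(path: str | Path) -> RunConfig:
    doc = yaml.safe_load(Path(path).read_text())
    if not isinstance(doc, dict) or doc.get("schema") != CONFIG_SCHEMA:
        raise SchemaError(f"{path}: not a {CONFIG_SCHEMA} document")
    return RunConfig.from_dict(doc)


def require_artifact(path: str | Path, producer: str) -> Path:
    """Error with the name of the producing script when an upstream
    artifact is missing."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(
            f"missing upstream artifact {path}; run {producer} first")
    return path
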