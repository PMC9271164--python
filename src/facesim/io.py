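"""File formats, run configuration, and seed management.

All tabular artifacts are plain CSV with explicit headers, prefixed by
``#``-comment lines carrying the package version, the stage seed and a hash
of the run configuration; floats are written with 17 significant digits so
write -> read round trips are exact.  Nested reports are JSON.  Run
configuration lives in JSON or YAML with an identical schema.

Every stochastic stage draws its seed deterministically from the master
seed through a counter scheme: stage i uses ``SeedSequence([master, i])``
with the stage order fixed in :data:`STAGES`, so stages can be re-run
independently and a master seed fully determines the pipeline.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .evaluation import CVSpec
from .facespace import FacePairStimulus, GeometricDesign, LatentVector, PairGeometry
from .synthetic_data import JudgmentDataset, ObserverSpec

__all__ = [
    "RunConfig",
    "STAGES",
    "stage_seed",
    "write_design",
    "read_design",
    "write_stimuli",
    "read_stimuli",
    "write_judgments",
    "read_judgments",
    "write_predictions",
    "read_predictions",
    "write_json",
]

FLOAT_FMT = "%.17g"

STAGES = ("design", "stimuli", "simulate", "predict", "evaluate", "identity", "geometry")


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage seed: SeedSequence([master, stage_index])."""
    idx = STAGES.index(stage)
    ss = np.random.SeedSequence([int(master_seed), idx])
    return int(ss.generate_state(1)[0] % (2**31))


# ---------------------------------------------------------------------------
# CSV plumbing


def _write_csv(df: pd.DataFrame, path, meta: dict | None = None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        fh.write("# facesim artifact\n")
        for k, v in (meta or {}).items():
            fh.write(f"# {k}: {v}\n")
        df.to_csv(fh, index=False, float_format=FLOAT_FMT)


def _read_csv(path) -> pd.DataFrame:
    # round_trip parsing: the default fast float parser can be off by 1 ulp
    return pd.read_csv(path, comment="#", float_precision="round_trip")


def _require(df: pd.DataFrame, columns, path) -> None:
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")


# ---------------------------------------------------------------------------
# Designs


def write_design(design: GeometricDesign, path, set_label: str = "A", meta=None) -> None:
    _write_csv(design.to_frame(set_label=set_label), path, meta)


def read_design(path) -> GeometricDesign:
    df = _read_csv(path)
    _require(df, ["pair_id", "r1", "r2", "theta_deg"], path)
    pairs = []
    for i, row in df.iterrows():
        try:
            pairs.append(PairGeometry(float(row.r1), float(row.r2), float(row.theta_deg)))
        except ValueError as exc:
            raise ValueError(f"{path}: invalid geometry at row {i}: {exc}") from exc
    radii = tuple(sorted(set(df.r1).union(df.r2)))
    angles = tuple(sorted(set(df.theta_deg)))
    return GeometricDesign(tuple(pairs), radii, angles)


# ---------------------------------------------------------------------------
# Stimuli (latent vectors)


def write_stimuli(stimuli, path, meta=None) -> None:
    dim = stimuli[0].v1.dim
    cols = [f"c{j:03d}" for j in range(dim)]
    rows = []
    for s in stimuli:
        for face_index, v in ((1, s.v1), (2, s.v2)):
            rows.append([s.pair_id, face_index, s.set_label, *v.coords])
    df = pd.DataFrame(rows, columns=["pair_id", "face_index", "set_label", *cols])
    _write_csv(df, path, meta)


def read_stimuli(path) -> list:
    from .facespace import pair_geometry_of

    df = _read_csv(path)
    _require(df, ["pair_id", "face_index", "set_label"], path)
    coord_cols = [c for c in df.columns if c.startswith("c")]
    out = []
    for pid, grp in df.groupby("pair_id", sort=True):
        grp = grp.sort_values("face_index")
        if list(grp.face_index) != [1, 2]:
            raise ValueError(f"{path}: pair {pid} does not have exactly faces 1 and 2")
        v1 = LatentVector(grp.iloc[0][coord_cols].to_numpy(dtype=float))
        v2 = LatentVector(grp.iloc[1][coord_cols].to_numpy(dtype=float))
        out.append(
            FacePairStimulus(
                int(pid), pair_geometry_of(v1, v2), v1, v2, set_label=str(grp.iloc[0].set_label)
            )
        )
    return out


# ---------------------------------------------------------------------------
# Judgments and predictions


def write_judgments(dataset: JudgmentDataset, path, meta=None) -> None:
    _write_csv(dataset.frame[list(JudgmentDataset.COLUMNS)], path, meta)


def read_judgments(path) -> JudgmentDataset:
    df = _read_csv(path)
    _require(df, JudgmentDataset.COLUMNS, path)
    try:
        return JudgmentDataset(df)
    except ValueError as exc:
        raise ValueError(f"{path}: {exc}") from exc


def write_predictions(predictions: pd.DataFrame, path, meta=None) -> None:
    long = predictions.reset_index().melt(
        id_vars="pair_id", var_name="model_name", value_name="distance"
    )
    _write_csv(long, path, meta)


def read_predictions(path) -> pd.DataFrame:
    df = _read_csv(path)
    _require(df, ["pair_id", "model_name", "distance"], path)
    neg = df["distance"] < 0
    if neg.any():
        raise ValueError(f"{path}: negative distance at row {int(np.flatnonzero(neg)[0])}")
    wide = df.pivot(index="pair_id", columns="model_name", values="distance")
    wide.columns.name = None
    return wide


def write_json(obj, path, meta=None) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        if isinstance(o, pd.Series):
            return o.to_dict()
        if isinstance(o, pd.DataFrame):
            return json.loads(o.to_json(orient="index"))
        raise TypeError(f"cannot serialize {type(o)}")

    payload = {"_meta": meta or {}, **obj} if isinstance(obj, dict) else obj
    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default, sort_keys=True)


# ---------------------------------------------------------------------------
# Run configuration


@dataclass
class RunConfig:
    """Everything a pipeline run needs, serializable round-trip."""

    master_seed: int = 0
    outdir: str = "facesim_out"
    # geometric design
    n_radii: int = 8
    max_radius: float = 40.0
    n_angles: int = 8
    dim: int = 398
    pairs_per_trial: int = 8
    # synthetic rendering
    n_landmarks: int = 30
    n_mesh_vertices: int = 150
    image_size: int = 32
    eigen_train: int = 300
    top_k: int = 50
    # observer population
    observer: ObserverSpec = field(default_factory=ObserverSpec)
    n_participants_b: int = 15
    # evaluation
    cv: CVSpec = field(default_factory=CVSpec)
    n_boot: int = 2000
    uniformity_bins: int = 5

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "RunConfig":
        d = dict(d)
        if "observer" in d and isinstance(d["observer"], dict):
            d["observer"] = ObserverSpec(**d["observer"])
        if "cv" in d and isinstance(d["cv"], dict):
            d["cv"] = CVSpec(**d["cv"])
        return cls(**d)

    def to_file(self, path) -> None:
        path = Path(path)
        path.parent.mkdir(parents=True, exist_ok=True)
        d = self.to_dict()
        if path.suffix in (".yaml", ".yml"):
            path.write_text(yaml.safe_dump(d, sort_keys=True))
        else:
            path.write_text(json.dumps(d, indent=2, sort_keys=True))

    @classmethod
    def from_file(cls, path) -> "RunConfig":
        path = Path(path)
        text = path.read_text()
        d = yaml.safe_load(text) if path.suffix in (".yaml", ".yml") else json.loads(text)
        return cls.from_dict(d)

    def config_hash(self) -> str:
        d = self.to_dict()
        d.pop("outdir", None)  # where results land is not part of the science
        canon = json.dumps(d, sort_keys=True)
        return hashlib.sha1(canon.encode()).hexdigest()[:12]

    def seed_for(self, stage: str) -> int:
        return stage_seed(self.master_seed, stage)

    def meta(self, stage: str) -> dict:
        return {
            "stage": stage,
            "seed": self.seed_for(stage),
            "config_hash": self.config_hash(),
        }
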