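"""CSV and configuration I/O.

Trajectory files are plain CSV with the exact header ``id,frame,x,y``
(comma-separated, UTF-8, '.' decimal); configuration files are YAML
mappings validated against the known parameter set.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field, fields
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .trajectory_analysis import TrajectoryDataset

__all__ = [
    "RunConfig",
    "read_trajectory_csv",
    "write_trajectory_csv",
    "write_polarization_csv",
    "load_config",
    "dump_config",
]

logger = logging.getLogger("bibswarm")

TRAJECTORY_HEADER = ["id", "frame", "x", "y"]


@dataclass
class RunConfig:
    """Every tunable parameter of the command-line workflows.

    Unknown keys are rejected at load time; physical parameters are
    range-checked.  ``mm_per_unit`` is carried as metadata and never
    silently applied to radii.
    """

    seed: int = 0
    out_dir: str = "."
    verbose: bool = False
    # inference
    n: int = 4
    p: float = 0.7
    M: int = 100
    mode: str = "bib"
    # toy sine environment
    baseline: float = 0.5
    amplitude: float = 0.4
    period: float = 3000.0
    horizon: int = 5000
    # trajectory analysis
    dt: float = 0.1
    r: float = 30.0
    mm_per_unit: float | None = 4.76
    # swarm simulation
    N: int = 100
    R: float = 30.0
    u: float = 1.0
    arena: float | None = None
    boundary: str = "periodic"
    order: str = "async"
    steps: int = 5000

    def __post_init__(self) -> None:
        if self.n < 2:
            raise ValueError("alphabet size n must be >= 2")
        if not (1.0 / self.n < self.p <= 1.0):
            raise ValueError(f"p={self.p} rejected: must lie in (1/{self.n}, 1]")
        for name in ("M", "horizon", "N", "steps"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be a positive integer")
        for name in ("dt", "r", "R", "u", "period"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.mode not in ("b", "bib"):
            raise ValueError(f"mode must be 'b' or 'bib', got {self.mode!r}")
        if self.boundary not in ("periodic", "reflecting"):
            raise ValueError(f"unknown boundary {self.boundary!r}")
        if self.order not in ("async", "sync"):
            raise ValueError(f"unknown update order {self.order!r}")


def load_config(path: str | Path | None = None, **overrides) -> RunConfig:
    """Load a YAML config, apply overrides, echo the effective values.

    An empty or absent file yields all defaults.  Unknown keys raise a
    ``ValueError`` naming the offenders.
    """
    data: dict = {}
    if path is not None:
        text = Path(path).read_text(encoding="utf-8")
        loaded = yaml.safe_load(text)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ValueError(f"config {path} must be a mapping, got {type(loaded).__name__}")
        data.update(loaded)
    data.update({k: v for k, v in overrides.items() if v is not None})
    known = {f.name for f in fields(RunConfig)}
    unknown = sorted(set(data) - known)
    if unknown:
        raise ValueError(f"unknown config keys: {', '.join(unknown)}")
    cfg = RunConfig(**data)
    logger.info("effective config: %s", dataclasses.asdict(cfg))
    return cfg


def dump_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(yaml.safe_dump(dataclasses.asdict(cfg)), encoding="utf-8")


def read_trajectory_csv(
    path: str | Path, dt: float = 0.1, mm_per_unit: float | None = None
) -> TrajectoryDataset:
    """Read an ``id,frame,x,y`` CSV into a validated dataset.

    Frames are sorted per individual; duplicate (id, frame) pairs and
    non-numeric coordinates are rejected with the offending line
    number.  Individuals absent at a frame are NaN-padded; a gap
    *inside* an individual's observed span is rejected by the dataset
    validator.
    """
    path = Path(path)
    df = pd.read_csv(path, dtype={"id": str})
    if list(df.columns) != TRAJECTORY_HEADER:
        raise ValueError(
            f"{path}: header must be exactly {','.join(TRAJECTORY_HEADER)}, "
            f"got {','.join(map(str, df.columns))}"
        )
    if df.empty:
        logger.warning("%s: no data rows, returning empty dataset", path)
        return TrajectoryDataset(positions=np.empty((0, 0, 2)), dt=dt, mm_per_unit=mm_per_unit)
    for col in ("frame", "x", "y"):
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = numeric.isna()
        if bad.any():
            line = int(bad.idxmax()) + 2  # header is line 1
            raise ValueError(f"{path}: non-numeric {col!r} at line {line}")
        df[col] = numeric
    if not (df["frame"] == df["frame"].astype(int)).all():
        raise ValueError(f"{path}: frame indices must be integers")
    df["frame"] = df["frame"].astype(int)
    dup = df.duplicated(subset=["id", "frame"])
    if dup.any():
        line = int(dup.idxmax()) + 2
        raise ValueError(f"{path}: duplicate (id, frame) at line {line}")
    ids = sorted(df["id"].unique())
    f_min, f_max = int(df["frame"].min()), int(df["frame"].max())
    T = f_max - f_min + 1
    positions = np.full((T, len(ids), 2), np.nan)
    col = {v: k for k, v in enumerate(ids)}
    positions[df["frame"].to_numpy() - f_min, df["id"].map(col).to_numpy()] = (
        df[["x", "y"]].to_numpy()
    )
    return TrajectoryDataset(positions=positions, dt=dt, ids=ids, mm_per_unit=mm_per_unit)


def write_trajectory_csv(traj: TrajectoryDataset, path: str | Path) -> None:
    """Write a dataset back to the ``id,frame,x,y`` dialect (observed
    frames only)."""
    rows = []
    for i, ident in enumerate(traj.ids):
        ok = np.isfinite(traj.positions[:, i]).all(axis=1)
        for t in np.flatnonzero(ok):
            rows.append((ident, int(t), traj.positions[t, i, 0], traj.positions[t, i, 1]))
    pd.DataFrame(rows, columns=TRAJECTORY_HEADER).to_csv(path, index=False)


def write_polarization_csv(psi: np.ndarray, n_included: np.ndarray, path: str | Path) -> None:
    pd.DataFrame(
        {"frame": np.arange(len(psi)), "psi": psi, "n_included": n_included}
    ).to_csv(path, index=False)
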