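"""Delimited-text readers and writers for fields, grids and profiles.

All formats are plain CSV with a small commented metadata header so that a
file round-trips without external sidecars:

    # x_extent=110.0
    # y_extent=60.0
    # cell_size=0.5
    # quantity=suction_MPa
    0.02,0.03,...
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .engine import CAGrid
from .metrics import BlockProfile
from .retention import SuctionField

__all__ = [
    "read_field",
    "write_field",
    "read_grid",
    "write_grid",
    "read_profile",
    "write_profile",
    "read_samples",
]


def _read_header(path: Path) -> tuple[dict[str, str], int]:
    meta: dict[str, str] = {}
    n = 0
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            n += 1
            body = line.lstrip("#").strip()
            if "=" in body:
                key, _, val = body.partition("=")
                meta[key.strip()] = val.strip()
    return meta, n


def _write_with_header(path: Path, meta: dict, array: np.ndarray, fmt: str) -> None:
    with open(path, "w") as fh:
        for key, val in meta.items():
            fh.write(f"# {key}={val}\n")
        np.savetxt(fh, array, delimiter=",", fmt=fmt)


def write_field(field: SuctionField, path) -> Path:
    path = Path(path)
    meta = {
        "x_extent": field.x_extent,
        "y_extent": field.y_extent,
        "cell_size": field.cell_size,
        "quantity": field.quantity,
    }
    _write_with_header(path, meta, field.values, "%.10g")
    return path


def read_field(path) -> SuctionField:
    path = Path(path)
    meta, skip = _read_header(path)
    values = np.loadtxt(path, delimiter=",", skiprows=skip, ndmin=2)
    return SuctionField(
        values=values,
        quantity=meta.get("quantity", "suction_MPa"),
        x_extent=float(meta.get("x_extent", 110.0)),
        y_extent=float(meta.get("y_extent", 60.0)),
        cell_size=float(meta.get("cell_size", 0.5)),
    )


def write_grid(grid: CAGrid, path) -> Path:
    path = Path(path)
    meta = {
        "x_extent": grid.x_extent,
        "y_extent": grid.y_extent,
        "cell_size": grid.cell_size,
        "step_count": grid.step_count,
        "rng_seed": grid.rng_seed,
    }
    _write_with_header(path, meta, grid.occupancy, "%d")
    return path


def read_grid(path) -> CAGrid:
    path = Path(path)
    meta, skip = _read_header(path)
    occ = np.loadtxt(path, delimiter=",", skiprows=skip, ndmin=2, dtype=int)
    return CAGrid(
        occupancy=occ,
        cell_size=float(meta.get("cell_size", 0.5)),
        x_extent=float(meta.get("x_extent", 110.0)),
        y_extent=float(meta.get("y_extent", 60.0)),
        step_count=int(meta.get("step_count", 0)),
        rng_seed=int(meta.get("rng_seed", 0)),
    )


def write_profile(profile: BlockProfile, path) -> Path:
    path = Path(path)
    meta = {
        "kind": profile.kind,
        "block_w": profile.block_w,
        "block_h": profile.block_h,
    }
    _write_with_header(path, meta, profile.values, "%.10g")
    return path


def read_profile(path) -> BlockProfile:
    path = Path(path)
    meta, skip = _read_header(path)
    values = np.loadtxt(path, delimiter=",", skiprows=skip, ndmin=2)
    return BlockProfile(
        values=values,
        kind=meta.get("kind", "observed"),
        block_w=float(meta.get("block_w", 15.0)),
        block_h=float(meta.get("block_h", 10.0)),
    )


def read_samples(path) -> np.ndarray:
    """Read a sparse sample file (columns x_cm, y_cm, value) as an array."""
    df = pd.read_csv(path, comment="#")
    required = ["x_cm", "y_cm", "value"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"sample file lacks columns: {missing}")
    return df[required].to_numpy(dtype=float)
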