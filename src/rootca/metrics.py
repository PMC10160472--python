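"""Validation and visualization.

Observed root densities come from soil slabs of 15 cm x 10 cm cross-section;
simulated grids are therefore aggregated over the same block tiling before
comparison.  Because the published validation compares *relative* density
profiles, both profiles are min-max normalized and the simulation error is
the mean absolute difference of the normalized profiles, in percent:

    error = 100 * mean |sim_norm - obs_norm|

Perfect agreement gives 0; a profile and its mirror give 100 on a two-level
profile.  Rendering writes portable graymap (PGM, binary P5) as the
byte-deterministic canonical raster, with optional PNG export.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np

from .engine import CAGrid
from .retention import DegenerateRangeError, minmax_normalize

__all__ = [
    "BlockProfile",
    "ComparisonResult",
    "coverage_by_block",
    "simulation_error",
    "profile_curves",
    "render_grid",
]


@dataclass
class BlockProfile:
    """Per-sampling-block root density over the domain.

    ``values`` holds occupied-cell counts for simulated grids and root
    length densities for observations; ``cells_per_block`` records each
    block's area in lattice cells so unequal edge blocks (the 110 cm pond is
    not a multiple of 15 cm) compare fairly on a per-area basis.
    """

    values: np.ndarray
    kind: str  # "simulated" | "observed"
    block_w: float = 15.0
    block_h: float = 10.0
    cells_per_block: np.ndarray | None = None
    has_partial_blocks: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("block values must be 2D")
        if np.any(self.values < 0):
            raise ValueError("block values must be non-negative")
        if self.kind not in ("simulated", "observed"):
            raise ValueError(f"unknown profile kind {self.kind!r}")
        if self.cells_per_block is not None:
            self.cells_per_block = np.asarray(self.cells_per_block, dtype=float)
            if self.cells_per_block.shape != self.values.shape:
                raise ValueError("cells_per_block shape mismatch")

    def density(self) -> np.ndarray:
        """Intensive per-block density (counts divided by block area in cells)."""
        if self.kind == "simulated" and self.cells_per_block is not None:
            return self.values / self.cells_per_block
        return self.values


def _block_edges(extent_cells: int, block_cells: float) -> list[tuple[int, int]]:
    edges = []
    start = 0
    step = int(round(block_cells))
    while start < extent_cells:
        edges.append((start, min(start + step, extent_cells)))
        start += step
    return edges


def coverage_by_block(
    grid: CAGrid, block_w: float = 15.0, block_h: float = 10.0
) -> BlockProfile:
    """Count occupied cells per sampling block.

    Block dimensions must be positive multiples of the cell size.  Partial
    edge blocks are kept and flagged; total counts sum to the occupied-cell
    count of the grid.
    """
    for dim in (block_w, block_h):
        if dim <= 0 or abs(dim / grid.cell_size - round(dim / grid.cell_size)) > 1e-9:
            raise ValueError(
                f"block dimension {dim} cm is not a positive multiple of the "
                f"{grid.cell_size} cm cell size"
            )
    nrow, ncol = grid.shape
    row_edges = _block_edges(nrow, block_h / grid.cell_size)
    col_edges = _block_edges(ncol, block_w / grid.cell_size)
    counts = np.zeros((len(row_edges), len(col_edges)))
    cells = np.zeros_like(counts)
    for i, (r0, r1) in enumerate(row_edges):
        for j, (c0, c1) in enumerate(col_edges):
            counts[i, j] = grid.occupancy[r0:r1, c0:c1].sum()
            cells[i, j] = (r1 - r0) * (c1 - c0)
    partial = bool(
        any(r1 - r0 != round(block_h / grid.cell_size) for r0, r1 in row_edges)
        or any(c1 - c0 != round(block_w / grid.cell_size) for c0, c1 in col_edges)
    )
    return BlockProfile(
        values=counts,
        kind="simulated",
        block_w=block_w,
        block_h=block_h,
        cells_per_block=cells,
        has_partial_blocks=partial,
    )


@dataclass
class ComparisonResult:
    """Profile comparison: normalized profiles and their mean absolute gap (%)."""

    error_percent: float
    sim_norm: np.ndarray
    obs_norm: np.ndarray
    per_block_abs_diff: np.ndarray = dc_field(default_factory=lambda: np.empty(0))


def simulation_error(sim: BlockProfile, obs: BlockProfile) -> ComparisonResult:
    """Normalized-profile simulation error between two block profiles.

    Each profile is reduced to per-area density, min-max normalized over its
    blocks, and compared by mean absolute difference scaled to percent.  The
    metric is symmetric and invariant to affine rescaling of either profile.
    """
    if sim.values.shape != obs.values.shape:
        raise ValueError(
            f"block grids differ: {sim.values.shape} vs {obs.values.shape}"
        )
    try:
        sim_norm = minmax_normalize(sim.density())
        obs_norm = minmax_normalize(obs.density())
    except DegenerateRangeError as exc:
        raise DegenerateRangeError(
            "constant block profile: normalized comparison undefined"
        ) from exc
    diff = np.abs(sim_norm - obs_norm)
    return ComparisonResult(
        error_percent=100.0 * float(diff.mean()),
        sim_norm=sim_norm,
        obs_norm=obs_norm,
        per_block_abs_diff=diff,
    )


def profile_curves(profile: BlockProfile, axis: str) -> np.ndarray:
    """1D marginal density of a block profile, min-max normalized.

    ``axis="horizontal"`` sums over depth to give one value per block
    column; ``axis="vertical"`` sums over columns for one value per depth
    layer.
    """
    if axis == "horizontal":
        marginal = profile.values.sum(axis=0)
    elif axis == "vertical":
        marginal = profile.values.sum(axis=1)
    else:
        raise ValueError(f"axis must be 'horizontal' or 'vertical', got {axis!r}")
    return minmax_normalize(marginal)


def render_grid(grid: CAGrid, path, zoom: int = 1, fmt: str | None = None) -> Path:
    """Write the occupancy lattice as a raster: roots dark on light soil.

    One lattice cell maps to ``zoom`` x ``zoom`` pixels.  PGM (binary P5)
    output is byte-deterministic for a fixed grid; PNG is available via
    Pillow when ``fmt="png"`` or the path ends in .png.
    """
    path = Path(path)
    if zoom < 1:
        raise ValueError("zoom must be >= 1")
    img = np.where(grid.occupancy > 0, 0, 255).astype(np.uint8)
    img = np.kron(img, np.ones((zoom, zoom), dtype=np.uint8))
    fmt = (fmt or path.suffix.lstrip(".") or "pgm").lower()
    if fmt == "pgm":
        header = f"P5\n{img.shape[1]} {img.shape[0]}\n255\n".encode("ascii")
        path.write_bytes(header + img.tobytes())
    elif fmt == "png":
        from PIL import Image

        Image.fromarray(img, mode="L").save(path, format="PNG")
    else:
        raise ValueError(f"unsupported raster format {fmt!r}")
    return path
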