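"""Cellular-automaton growth core.

Binary root-occupancy dynamics on a 0.5 cm lattice.  Each cell is either
root (1) or soil (0) and the transition is irreversible (no 1 -> 0).  New
root cells appear only on the growth frontier: empty cells that a root can
reach through one of the five non-upward Moore directions

    W, E, SW, S, SE

so gravitropism is encoded as the missing upward moves while hydrotropism
enters through the sampling weights: each step flips ``k`` frontier cells
drawn without replacement with probability proportional to the (clamped)
driving-law value at the candidate cell.  Plants share one pooled frontier,
so competition between neighbouring root systems emerges from the shared
moisture field rather than an explicit interaction term.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field as dc_field

import numpy as np

from .driving import DrivingParams, target_occupancy, weight_field
from .retention import SuctionField

__all__ = [
    "CAGrid",
    "PlantLayout",
    "GrowthConfig",
    "StalledGrowthWarning",
    "ALLOWED_DIRECTIONS",
    "init_grid",
    "frontier",
    "frontier_mask",
    "growth_step",
    "run_simulation",
]

#: Allowed growth moves as (drow, dcol) offsets from an occupied cell:
#: W, E, SW, S, SE.  Rows grow downward; upward moves are excluded.
ALLOWED_DIRECTIONS: tuple[tuple[int, int], ...] = (
    (0, -1),
    (0, 1),
    (1, -1),
    (1, 0),
    (1, 1),
)


class StalledGrowthWarning(UserWarning):
    """Growth stalled: every frontier cell has zero weight."""


@dataclass
class PlantLayout:
    """Stem positions along the pond, ordered by distance from the irrigation point."""

    plant_xs: tuple[float, ...]
    spacing_cm: float
    irrigation_x: float = 0.0
    taproot_depth: float = 40.0

    def __post_init__(self) -> None:
        self.plant_xs = tuple(
            sorted(self.plant_xs, key=lambda x: abs(x - self.irrigation_x))
        )
        if self.taproot_depth < 0:
            raise ValueError("taproot_depth must be non-negative")


@dataclass
class GrowthConfig:
    """Knobs of the growth loop.

    ``kappa`` converts mean root length density into an occupancy target,
    ``gamma`` sharpens the moisture weights, ``cells_per_step`` is the batch
    size of each stochastic accretion step, and ``rng_seed`` makes the whole
    run reproducible.
    """

    driving: DrivingParams
    kappa: float = 2.1e-5
    gamma: float = 1.0
    cells_per_step: int = 25
    max_steps: int = 100_000
    rng_seed: int = 0
    stop: str = "target_occupancy"  # or "frontier_exhausted"
    capacity_tile_cm: float | None = 5.0
    lateral_boost: float = 1.0
    sprout_rate: float = 0.01

    def __post_init__(self) -> None:
        if self.kappa <= 0 or self.gamma < 0:
            raise ValueError("kappa must be positive and gamma non-negative")
        if self.capacity_tile_cm is not None and self.capacity_tile_cm <= 0:
            raise ValueError("capacity_tile_cm must be positive (or None)")
        if self.lateral_boost < 0 or self.sprout_rate < 0:
            raise ValueError("lateral_boost and sprout_rate must be non-negative")
        if self.cells_per_step < 1 or self.max_steps < 1:
            raise ValueError("cells_per_step and max_steps must be >= 1")
        if self.stop not in ("target_occupancy", "frontier_exhausted"):
            raise ValueError(f"unknown stop rule {self.stop!r}")


@dataclass
class CAGrid:
    """Binary occupancy lattice with its seed cells and step counter."""

    occupancy: np.ndarray
    cell_size: float = 0.5
    x_extent: float = 110.0
    y_extent: float = 60.0
    seed_cells: list[tuple[int, int]] = dc_field(default_factory=list)
    step_count: int = 0
    rng_seed: int = 0

    def __post_init__(self) -> None:
        self.occupancy = np.asarray(self.occupancy, dtype=np.uint8)
        if self.occupancy.ndim != 2:
            raise ValueError("occupancy must be 2D")
        if not np.isin(self.occupancy, (0, 1)).all():
            raise ValueError("occupancy states must be 0 or 1")

    @property
    def shape(self) -> tuple[int, int]:
        return self.occupancy.shape

    @property
    def occupied_count(self) -> int:
        return int(self.occupancy.sum())

    def col_of_x(self, x_cm: float) -> int:
        return min(int(x_cm / self.cell_size), self.shape[1] - 1)


def init_grid(layout: PlantLayout, field: SuctionField) -> CAGrid:
    """Seed the lattice: one surface cell per stem plus its taproot column.

    The main (tap) root is pre-occupied as a vertical column down to
    ``layout.taproot_depth``; lateral growth then accretes from these seed
    cells.
    """
    nrow, ncol = field.shape
    if layout.taproot_depth > field.y_extent:
        raise ValueError("taproot_depth exceeds the domain depth")
    occ = np.zeros((nrow, ncol), dtype=np.uint8)
    seeds: list[tuple[int, int]] = []
    for x in layout.plant_xs:
        if not (0 <= x <= field.x_extent):
            raise ValueError(f"plant at x={x} cm lies outside the {field.x_extent} cm domain")
        col = min(int(x / field.cell_size), ncol - 1)
        depth_rows = max(1, round(layout.taproot_depth / field.cell_size))
        depth_rows = min(depth_rows, nrow)
        for row in range(depth_rows):
            occ[row, col] = 1
            seeds.append((col, row))
    return CAGrid(
        occupancy=occ,
        cell_size=field.cell_size,
        x_extent=field.x_extent,
        y_extent=field.y_extent,
        seed_cells=seeds,
    )


def _shift(arr: np.ndarray, drow: int, dcol: int) -> np.ndarray:
    """Shift a boolean grid by (drow, dcol), padding with False."""
    out = np.zeros_like(arr)
    rs = slice(max(drow, 0), arr.shape[0] + min(drow, 0))
    cs = slice(max(dcol, 0), arr.shape[1] + min(dcol, 0))
    rs_src = slice(max(-drow, 0), arr.shape[0] + min(-drow, 0))
    cs_src = slice(max(-dcol, 0), arr.shape[1] + min(-dcol, 0))
    out[rs, cs] = arr[rs_src, cs_src]
    return out


def frontier_mask(grid: CAGrid) -> np.ndarray:
    """Boolean mask of empty cells adjacent to roots via an allowed move."""
    occ = grid.occupancy.astype(bool)
    cand = np.zeros_like(occ)
    for drow, dcol in ALLOWED_DIRECTIONS:
        cand |= _shift(occ, drow, dcol)
    return cand & ~occ


def _lateral_masks(occupancy: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Lateral-axis extension and sprout candidates.

    A *run* candidate continues an existing horizontal root axis: its only
    occupied parent (cells able to grow into it: E, W, NE, N, NW) is a
    horizontal neighbour backed by a second collinear cell.  A *sprout*
    candidate starts a new lateral off a root flank.  Boosting runs over
    sprouts yields a few long, nearly horizontal laterals — the morphology
    cotton root systems show under one-sided irrigation — instead of many
    short stubs.
    """
    occ = occupancy.astype(bool)
    n_parents = np.zeros(occ.shape, dtype=np.int8)
    for drow, dcol in ALLOWED_DIRECTIONS:
        n_parents += _shift(occ, drow, dcol)
    unique = n_parents == 1
    east_par = _shift(occ, 0, -1)  # occupied cell east of the candidate
    west_par = _shift(occ, 0, 1)
    run_w = unique & east_par & _shift(occ, 0, -2)
    run_e = unique & west_par & _shift(occ, 0, 2)
    runs = run_w | run_e
    sprouts = unique & (east_par | west_par) & ~runs
    return runs, sprouts


def frontier(grid: CAGrid) -> set[tuple[int, int]]:
    """Candidate cells as a set of (row, col) pairs."""
    rows, cols = np.nonzero(frontier_mask(grid))
    return set(zip(rows.tolist(), cols.tolist()))


def growth_step(
    grid: CAGrid, weights: np.ndarray, k: int, rng: np.random.Generator
) -> CAGrid:
    """One stochastic accretion step: flip up to ``k`` frontier cells to root.

    Cells are drawn without replacement with probability proportional to
    their weight; zero-weight candidates are never chosen.  Mutates and
    returns ``grid``.  If every frontier cell has zero weight the grid is
    returned unchanged and a :class:`StalledGrowthWarning` is issued.
    """
    if weights.shape != grid.shape:
        raise ValueError("weights shape must match the grid")
    if k < 1:
        raise ValueError("k must be >= 1")
    mask = frontier_mask(grid)
    rows, cols = np.nonzero(mask)
    if rows.size == 0:
        warnings.warn("frontier is empty", StalledGrowthWarning, stacklevel=2)
        return grid
    w = weights[rows, cols]
    total = w.sum()
    if total <= 0:
        warnings.warn(
            "all frontier weights are zero; growth stalled",
            StalledGrowthWarning,
            stacklevel=2,
        )
        return grid
    n_pos = int((w > 0).sum())
    n_pick = min(k, n_pos)
    idx = rng.choice(rows.size, size=n_pick, replace=False, p=w / total)
    grid.occupancy[rows[idx], cols[idx]] = 1
    grid.step_count += 1
    return grid


class _TileCapacity:
    """Per-tile root capacity derived from the driving law.

    The driving law is treated as a local carrying capacity: the domain is
    partitioned into square tiles and each tile receives a quota of root
    cells proportional to its share of the (clamped) driving weight, so that
    the lattice's coverage density converges toward the root-length-density
    profile as the quota fills.  A frontier cell's effective weight is its
    tile's remaining quota.
    """

    def __init__(self, weights: np.ndarray, tile_cells: int, target: int) -> None:
        nrow, ncol = weights.shape
        self.row_id = np.minimum(
            np.arange(nrow) // tile_cells, (nrow - 1) // tile_cells
        )
        self.col_id = np.minimum(
            np.arange(ncol) // tile_cells, (ncol - 1) // tile_cells
        )
        ntr, ntc = self.row_id[-1] + 1, self.col_id[-1] + 1
        tile_w = np.zeros((ntr, ntc))
        np.add.at(tile_w, (self.row_id[:, None], self.col_id[None, :]), weights)
        total = tile_w.sum()
        self.quota = target * tile_w / total if total > 0 else tile_w
        self.shape = weights.shape

    def per_cell_quota(self) -> np.ndarray:
        """The tile quota broadcast to every cell of the tile."""
        return self.quota[self.row_id[:, None], self.col_id[None, :]]

    def remaining(self, occupancy: np.ndarray) -> np.ndarray:
        """Per-cell unfilled quota of the cell's tile (clamped at zero)."""
        occ_tile = np.zeros_like(self.quota)
        np.add.at(
            occ_tile,
            (self.row_id[:, None], self.col_id[None, :]),
            occupancy.astype(float),
        )
        rem = np.maximum(0.0, self.quota - occ_tile)
        return rem[self.row_id[:, None], self.col_id[None, :]]


def run_simulation(
    layout: PlantLayout, field: SuctionField, cfg: GrowthConfig
) -> tuple[CAGrid, list[int]]:
    """The full growth loop.

    Seeds the lattice, derives the driving weights and the occupancy target,
    and repeats :func:`growth_step` until the target is reached, the
    frontier exhausts, or ``max_steps`` elapse.  Returns the final grid and
    the per-step occupied-count history (initial count first; non-
    decreasing).

    With the default tile-capacity rule (``cfg.capacity_tile_cm`` set) the
    sampling weights are refreshed every step from two terms: the unfilled
    quota of each tile (each tile holds a root-cell quota proportional to
    its driving weight, so occupied density converges toward the
    driving-law profile wherever growth reaches), plus a lateral-axis term
    that boosts candidates extending an existing horizontal root axis
    (``lateral_boost``) or starting a new one off a flank (``sprout_rate``),
    which lets a few long laterals carry the root system across the domain.
    ``capacity_tile_cm = None`` uses the static driving weights instead
    (pure moisture-biased accretion).
    """
    grid = init_grid(layout, field)
    grid.rng_seed = cfg.rng_seed
    weights = weight_field(field, cfg.driving, gamma=cfg.gamma)
    target = target_occupancy(field, cfg.driving, cfg.kappa)
    capacity = None
    if cfg.capacity_tile_cm is not None:
        tile_cells = max(1, round(cfg.capacity_tile_cm / field.cell_size))
        capacity = _TileCapacity(weights, tile_cells, target)
    rng = np.random.default_rng(cfg.rng_seed)
    history = [grid.occupied_count]
    for _ in range(cfg.max_steps):
        if cfg.stop == "target_occupancy" and grid.occupied_count >= target:
            break
        before = grid.occupied_count
        if capacity is None:
            step_w = weights
        else:
            runs, sprouts = _lateral_masks(grid.occupancy)
            axis = cfg.lateral_boost * runs + cfg.sprout_rate * sprouts
            step_w = capacity.remaining(grid.occupancy) + capacity.per_cell_quota() * axis
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", StalledGrowthWarning)
            budget = cfg.cells_per_step
            if cfg.stop == "target_occupancy":
                budget = min(budget, target - before)
            grid = growth_step(grid, step_w, budget, rng)
        history.append(grid.occupied_count)
        if grid.occupied_count == before:  # frontier exhausted or stalled
            if cfg.stop == "target_occupancy" and before < max(1, target) * 0.1:
                warnings.warn(
                    f"growth stalled at {before} of {target} target cells; "
                    "the weight field is likely degenerate",
                    StalledGrowthWarning,
                    stacklevel=2,
                )
            break
    return grid, history
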