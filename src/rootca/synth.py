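"""Synthetic study fixtures.

Generates the inputs the simulator consumes without any field measurement:

* a parametric *wetting bulb* — the suction field around a lateral point
  irrigation source, minimal at the source and rising with (anisotropic)
  distance until it clamps at the far-field value;
* default three-plant layouts for the 30 cm and 15 cm spacing treatments;
* noisy "observed" block density profiles derived from a driving law, used
  as stand-ins for slab-sampled root densities in validation runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .driving import DrivingParams, rld_from_suction
from .engine import PlantLayout
from .metrics import BlockProfile, _block_edges
from .retention import SuctionField, minmax_normalize

__all__ = [
    "BulbParams",
    "BULB_PRESETS",
    "wetting_bulb",
    "default_layout",
    "synth_observed",
]


@dataclass(frozen=True)
class BulbParams:
    """Wetting-bulb shape parameters.

    Suction is ``s_min`` at the source (x0, y0) and rises as
    ``s_min + (s_max - s_min) * min(1, r**exponent)`` with the elliptic
    radius ``r = sqrt(((x-x0)/radius_x)**2 + ((y-y0)/radius_y)**2)``.
    The default source depth of 10 cm places the wettest zone in the shallow
    layer next to the pond wall.
    """

    source_x: float = 0.0
    source_y: float = 10.0
    s_min: float = 0.02
    s_max: float = 2.5
    radius_x: float = 90.0
    radius_y: float = 45.0
    exponent: float = 1.5

    def __post_init__(self) -> None:
        if not self.s_min < self.s_max:
            raise ValueError("s_min must be below s_max")
        if self.radius_x <= 0 or self.radius_y <= 0:
            raise ValueError("radii must be positive")
        if self.exponent <= 0:
            raise ValueError("exponent must be positive")
        if self.s_min < 0:
            raise ValueError("suction cannot be negative")


#: Canonical bulb states: a fresh large bulb shortly after irrigation and
#: the shrunken, drier state a few days later.
BULB_PRESETS: dict[str, BulbParams] = {
    "12h": BulbParams(s_min=0.02, s_max=2.5, radius_x=100.0, radius_y=55.0, exponent=1.5),
    "3d": BulbParams(s_min=0.3, s_max=4.0, radius_x=45.0, radius_y=25.0, exponent=1.2),
}


def wetting_bulb(
    params: BulbParams = BULB_PRESETS["12h"],
    x_extent: float = 110.0,
    y_extent: float = 60.0,
    cell_size: float = 0.5,
) -> SuctionField:
    """Synthesize a point-source suction field on the simulation lattice."""
    nrow = round(y_extent / cell_size)
    ncol = round(x_extent / cell_size)
    x = (np.arange(ncol) + 0.5) * cell_size
    y = (np.arange(nrow) + 0.5) * cell_size
    X, Y = np.meshgrid(x, y)
    r = np.sqrt(
        ((X - params.source_x) / params.radius_x) ** 2
        + ((Y - params.source_y) / params.radius_y) ** 2
    )
    S = params.s_min + (params.s_max - params.s_min) * np.minimum(1.0, r**params.exponent)
    return SuctionField(
        values=S,
        quantity="suction_MPa",
        x_extent=x_extent,
        y_extent=y_extent,
        cell_size=cell_size,
    )


def default_layout(spacing: int, taproot_depth: float = 40.0) -> PlantLayout:
    """Three-plant layout for a spacing treatment.

    30 cm spacing puts the stems at 25, 55 and 85 cm from the irrigation
    wall (the far plant inside the 70-100 cm bracket); 15 cm spacing packs
    them at 20, 35 and 50 cm, all within 50 cm of the source.
    """
    if spacing == 30:
        xs = (25.0, 55.0, 85.0)
    elif spacing == 15:
        xs = (20.0, 35.0, 50.0)
    else:
        raise ValueError(f"spacing must be 30 or 15 cm, got {spacing}")
    return PlantLayout(plant_xs=xs, spacing_cm=float(spacing), taproot_depth=taproot_depth)


def synth_observed(
    field: SuctionField,
    p: DrivingParams,
    sigma: float = 0.0,
    rng: np.random.Generator | None = None,
    block_w: float = 15.0,
    block_h: float = 10.0,
) -> BlockProfile:
    """Noisy "observed" block densities generated from a driving law.

    Each block value is the mean clamped driving-law RLD over the block's
    cells, multiplied by unit-mean lognormal noise of relative standard
    deviation ``sigma``.
    """
    if sigma < 0:
        raise ValueError("sigma must be non-negative")
    rng = np.random.default_rng() if rng is None else rng
    rld = np.maximum(0.0, rld_from_suction(minmax_normalize(field.values), p))
    nrow, ncol = field.shape
    row_edges = _block_edges(nrow, block_h / field.cell_size)
    col_edges = _block_edges(ncol, block_w / field.cell_size)
    values = np.zeros((len(row_edges), len(col_edges)))
    for i, (r0, r1) in enumerate(row_edges):
        for j, (c0, c1) in enumerate(col_edges):
            values[i, j] = rld[r0:r1, c0:c1].mean()
    if sigma > 0:
        # lognormal with exact unit mean and relative sd sigma
        s_log = np.sqrt(np.log1p(sigma**2))
        noise = rng.lognormal(mean=-0.5 * s_log**2, sigma=s_log, size=values.shape)
        values = values * noise
    return BlockProfile(
        values=values, kind="observed", block_w=block_w, block_h=block_h
    )
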