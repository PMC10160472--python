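"""Scenario configuration and the end-to-end runner.

A scenario is one YAML file naming the plant layout, the suction field
source (a wetting-bulb preset or a field file), the driving-law preset or
explicit coefficients, and the growth knobs.  ``run_scenario`` executes the
whole pipeline — field preparation, weights, simulation, block metrics,
raster — and writes a machine-readable run summary.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import yaml

from . import io as rio
from .driving import DRIVING_PRESETS, DrivingParams, target_occupancy, weight_field
from .engine import GrowthConfig, PlantLayout, run_simulation
from .metrics import coverage_by_block, render_grid, simulation_error
from .retention import DEFAULT_RETENTION, RetentionParams, SuctionField
from .synth import BULB_PRESETS, default_layout, wetting_bulb

__all__ = ["ScenarioConfig", "load_config", "run_scenario"]

log = logging.getLogger("rootca")

_KNOWN_KEYS = {
    "driving_preset",
    "driving",
    "layout",
    "spacing_cm",
    "taproot_depth",
    "field_file",
    "bulb_preset",
    "bulb",
    "retention",
    "kappa",
    "gamma",
    "cells_per_step",
    "max_steps",
    "rng_seed",
    "stop",
    "capacity_tile_cm",
    "lateral_boost",
    "sprout_rate",
    "block_w",
    "block_h",
    "observed_profile",
    "output_dir",
}


@dataclass
class ScenarioConfig:
    """Fully resolved scenario: everything a run needs, reproducibly."""

    driving: DrivingParams
    layout: PlantLayout
    field: SuctionField
    retention: RetentionParams = DEFAULT_RETENTION
    growth: GrowthConfig = None  # type: ignore[assignment]
    block_w: float = 15.0
    block_h: float = 10.0
    observed_profile: Path | None = None
    output_dir: Path = Path("rootca_out")
    raw: dict = dc_field(default_factory=dict)


def _resolve_driving(cfg: dict) -> DrivingParams:
    if "driving_preset" in cfg:
        name = cfg["driving_preset"]
        if name not in DRIVING_PRESETS:
            raise ValueError(
                f"unknown driving preset {name!r}; available: {sorted(DRIVING_PRESETS)}"
            )
        return DRIVING_PRESETS[name]
    if "driving" in cfg:
        return DrivingParams(**cfg["driving"])
    raise ValueError("config must set driving_preset or driving")


def load_config(path) -> ScenarioConfig:
    """Load, validate and fully resolve a scenario YAML file.

    Unknown keys are rejected by name; ``rng_seed`` is mandatory so no run
    is silently nondeterministic.  The resolved configuration is echoed to
    the log.
    """
    path = Path(path)
    with open(path) as fh:
        cfg = yaml.safe_load(fh) or {}
    if not isinstance(cfg, dict):
        raise ValueError("config root must be a mapping")
    unknown = sorted(set(cfg) - _KNOWN_KEYS)
    if unknown:
        raise ValueError(f"unknown config keys: {unknown}")
    if "rng_seed" not in cfg:
        raise ValueError("config must set rng_seed explicitly")

    driving = _resolve_driving(cfg)

    taproot = float(cfg.get("taproot_depth", 40.0))
    if "layout" in cfg:
        lay = cfg["layout"]
        layout = PlantLayout(
            plant_xs=tuple(lay["plant_xs"]),
            spacing_cm=float(lay.get("spacing_cm", 0.0)),
            irrigation_x=float(lay.get("irrigation_x", 0.0)),
            taproot_depth=float(lay.get("taproot_depth", taproot)),
        )
    else:
        spacing = int(cfg.get("spacing_cm", driving.spacing_cm or 30))
        layout = default_layout(spacing, taproot_depth=taproot)

    if "field_file" in cfg:
        field = rio.read_field(cfg["field_file"])
    elif "bulb" in cfg:
        from .synth import BulbParams

        field = wetting_bulb(BulbParams(**cfg["bulb"]))
    else:
        preset = cfg.get("bulb_preset", "12h")
        if preset not in BULB_PRESETS:
            raise ValueError(
                f"unknown bulb preset {preset!r}; available: {sorted(BULB_PRESETS)}"
            )
        field = wetting_bulb(BULB_PRESETS[preset])

    retention = (
        RetentionParams(**cfg["retention"]) if "retention" in cfg else DEFAULT_RETENTION
    )
    growth = GrowthConfig(
        driving=driving,
        kappa=float(cfg.get("kappa", 2.1e-5)),
        gamma=float(cfg.get("gamma", 1.0)),
        cells_per_step=int(cfg.get("cells_per_step", 25)),
        max_steps=int(cfg.get("max_steps", 100_000)),
        rng_seed=int(cfg["rng_seed"]),
        stop=cfg.get("stop", "target_occupancy"),
        capacity_tile_cm=(
            None
            if cfg.get("capacity_tile_cm", 5.0) is None
            else float(cfg.get("capacity_tile_cm", 5.0))
        ),
        lateral_boost=float(cfg.get("lateral_boost", 1.0)),
        sprout_rate=float(cfg.get("sprout_rate", 0.01)),
    )
    observed = Path(cfg["observed_profile"]) if "observed_profile" in cfg else None
    if observed is not None and not observed.exists():
        raise FileNotFoundError(f"observed profile not found: {observed}")
    resolved = ScenarioConfig(
        driving=driving,
        layout=layout,
        field=field,
        retention=retention,
        growth=growth,
        block_w=float(cfg.get("block_w", 15.0)),
        block_h=float(cfg.get("block_h", 10.0)),
        observed_profile=observed,
        output_dir=Path(cfg.get("output_dir", "rootca_out")),
        raw=cfg,
    )
    log.info("resolved scenario: %s", json.dumps(_echo(resolved), sort_keys=True))
    return resolved


def _echo(cfg: ScenarioConfig) -> dict:
    return {
        "driving": vars(cfg.driving).copy(),
        "plant_xs": list(cfg.layout.plant_xs),
        "taproot_depth": cfg.layout.taproot_depth,
        "kappa": cfg.growth.kappa,
        "gamma": cfg.growth.gamma,
        "cells_per_step": cfg.growth.cells_per_step,
        "rng_seed": cfg.growth.rng_seed,
        "block_w": cfg.block_w,
        "block_h": cfg.block_h,
    }


def run_scenario(cfg: ScenarioConfig) -> dict:
    """Run the full pipeline and write artifacts into ``cfg.output_dir``.

    Writes occupancy.csv, render.pgm, profile.csv and summary.json; the
    summary includes the occupied count, the target, the step count, and
    the comparison error when an observed profile is configured.  Partial
    outputs are removed if any stage fails.
    """
    out = cfg.output_dir
    out.mkdir(parents=True, exist_ok=True)
    written: list[Path] = []
    try:
        weights = weight_field(cfg.field, cfg.driving, gamma=cfg.growth.gamma)
        log.info(
            "weight field: min=%.4g max=%.4g zero-share=%.3f",
            weights.min(),
            weights.max(),
            float((weights == 0).mean()),
        )
        target = target_occupancy(cfg.field, cfg.driving, cfg.growth.kappa)
        log.info("occupancy target: %d cells", target)
        grid, history = run_simulation(cfg.layout, cfg.field, cfg.growth)
        log.info("simulation: %d steps, %d occupied", grid.step_count, grid.occupied_count)
        profile = coverage_by_block(grid, cfg.block_w, cfg.block_h)

        written.append(rio.write_grid(grid, out / "occupancy.csv"))
        written.append(rio.write_profile(profile, out / "profile.csv"))
        written.append(render_grid(grid, out / "render.pgm"))
        np.savetxt(out / "history.csv", np.asarray(history, dtype=int), fmt="%d")
        written.append(out / "history.csv")

        summary = {
            "occupied_cells": grid.occupied_count,
            "target_occupancy": target,
            "steps": grid.step_count,
            "rng_seed": cfg.growth.rng_seed,
            "config": _echo(cfg),
        }
        if cfg.observed_profile is not None:
            obs = rio.read_profile(cfg.observed_profile)
            result = simulation_error(profile, obs)
            summary["error_percent"] = result.error_percent
            log.info("simulation error: %.2f%%", result.error_percent)
        with open(out / "summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        written.append(out / "summary.json")
        return summary
    except Exception:
        for p in written:
            p.unlink(missing_ok=True)
        raise
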