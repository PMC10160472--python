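"""CA growth core: seeding, frontier geometry, stochastic accretion, full runs."""

import numpy as np
import pytest

from rootca import (
    CAGrid,
    GrowthConfig,
    PlantLayout,
    SuctionField,
    frontier,
    growth_step,
    init_grid,
    run_simulation,
    wetting_bulb,
)
from rootca.engine import ALLOWED_DIRECTIONS, StalledGrowthWarning


def tiny_field(nrow=8, ncol=8, cell=0.5):
    vals = np.tile(np.linspace(0.1, 0.9, ncol), (nrow, 1))
    return SuctionField(vals, x_extent=ncol * cell, y_extent=nrow * cell, cell_size=cell)


def single_seed_grid(nrow=5, ncol=5, row=2, col=2):
    occ = np.zeros((nrow, ncol), dtype=np.uint8)
    occ[row, col] = 1
    return CAGrid(occ, x_extent=ncol * 0.5, y_extent=nrow * 0.5, seed_cells=[(col, row)])


class TestInitGrid:
    def test_three_plants_shallow_taproot(self):
        layout = PlantLayout(plant_xs=(0.5, 1.5, 2.5), spacing_cm=1.0, taproot_depth=0.5)
        grid = init_grid(layout, tiny_field())
        assert grid.occupied_count == 3
        assert all(grid.occupancy[0, c] == 1 for c in (1, 3, 5))

    def test_full_depth_taproot_spans_all_rows(self):
        layout = PlantLayout(plant_xs=(2.0,), spacing_cm=0, taproot_depth=4.0)
        grid = init_grid(layout, tiny_field())
        assert grid.occupancy[:, 4].sum() == 8

    def test_plant_outside_domain_rejected(self):
        layout = PlantLayout(plant_xs=(115.0,), spacing_cm=0)
        with pytest.raises(ValueError):
            init_grid(layout, wetting_bulb())


class TestFrontier:
    def test_interior_cell_has_five_candidates(self):
        grid = single_seed_grid()
        cand = frontier(grid)
        assert cand == {(2, 1), (2, 3), (3, 1), (3, 2), (3, 3)}

    def test_bottom_left_corner_has_one_candidate(self):
        grid = single_seed_grid(row=4, col=0)
        assert frontier(grid) == {(4, 1)}

    def test_full_grid_has_empty_frontier(self):
        occ = np.ones((4, 4), dtype=np.uint8)
        assert frontier(CAGrid(occ, x_extent=2, y_extent=2)) == set()


class TestGrowthStep:
    def test_uniform_weights_match_enumeration(self):
        """Single-step choice frequencies equal the exact uniform 1/5 law."""
        counts = {}
        weights = np.ones((5, 5))
        rng = np.random.default_rng(12345)
        n = 100_000
        for _ in range(n):
            grid = single_seed_grid()
            growth_step(grid, weights, k=1, rng=rng)
            grid.occupancy[2, 2] = 0
            cell = tuple(np.argwhere(grid.occupancy)[0])
            counts[cell] = counts.get(cell, 0) + 1
        assert set(counts) == {(2, 1), (2, 3), (3, 1), (3, 2), (3, 3)}
        for c, ct in counts.items():
            assert abs(ct / n - 0.2) < 0.005, (c, ct / n)

    def test_single_positive_weight_always_chosen(self):
        weights = np.zeros((5, 5))
        weights[3, 2] = 4.2
        for seed in range(10):
            grid = single_seed_grid()
            growth_step(grid, weights, k=1, rng=np.random.default_rng(seed))
            assert grid.occupancy[3, 2] == 1
            assert grid.occupied_count == 2

    def test_same_seed_reproduces_occupancy(self):
        weights = np.random.default_rng(0).random((5, 5))
        outs = []
        for _ in range(2):
            grid = single_seed_grid()
            rng = np.random.default_rng(99)
            for _ in range(4):
                growth_step(grid, weights, k=2, rng=rng)
            outs.append(grid.occupancy.copy())
        assert np.array_equal(outs[0], outs[1])

    def test_zero_weights_signal_stall(self):
        grid = single_seed_grid()
        with pytest.warns(StalledGrowthWarning):
            growth_step(grid, np.zeros((5, 5)), k=1, rng=np.random.default_rng(0))
        assert grid.occupied_count == 1
        assert grid.step_count == 0


def _assert_connected_via_allowed(grid):
    """Every occupied cell must be reachable from a seed using allowed moves."""
    occ = grid.occupancy.astype(bool)
    reach = np.zeros_like(occ)
    for col, row in grid.seed_cells:
        reach[row, col] = True
    changed = True
    while changed:
        changed = False
        for drow, dcol in ALLOWED_DIRECTIONS:
            shifted = np.zeros_like(reach)
            rs = slice(max(drow, 0), occ.shape[0] + min(drow, 0))
            cs = slice(max(dcol, 0), occ.shape[1] + min(dcol, 0))
            rs_src = slice(max(-drow, 0), occ.shape[0] + min(-drow, 0))
            cs_src = slice(max(-dcol, 0), occ.shape[1] + min(-dcol, 0))
            shifted[rs, cs] = reach[rs_src, cs_src]
            new = shifted & occ & ~reach
            if new.any():
                reach |= new
                changed = True
    assert np.array_equal(reach, occ)


class TestRunSimulation:
    def test_target_below_seed_count_returns_immediately(self, boll_log):
        layout = PlantLayout(plant_xs=(1.0,), spacing_cm=0, taproot_depth=4.0)
        cfg = GrowthConfig(driving=boll_log, kappa=1e-9, rng_seed=0)
        grid, history = run_simulation(layout, tiny_field(), cfg)
        assert grid.step_count == 0
        assert history == [grid.occupied_count]

    def test_reaches_target_exactly_and_monotone_history(self, default_scenario):
        field, layout, cfg = default_scenario
        grid, history = run_simulation(layout, field, cfg)
        from rootca import target_occupancy

        assert grid.occupied_count == target_occupancy(field, cfg.driving, cfg.kappa)
        assert all(b >= a for a, b in zip(history, history[1:]))

    def test_connectivity_through_allowed_directions_only(self, default_scenario):
        field, layout, cfg = default_scenario
        grid, _ = run_simulation(layout, field, cfg)
        _assert_connected_via_allowed(grid)

    def test_rerun_with_same_seed_is_identical(self, default_scenario):
        field, layout, cfg = default_scenario
        g1, h1 = run_simulation(layout, field, cfg)
        g2, h2 = run_simulation(layout, field, cfg)
        assert np.array_equal(g1.occupancy, g2.occupancy)
        assert h1 == h2

    def test_mirror_symmetric_field_gives_symmetric_growth(self, boll_exp):
        """On a field and layout symmetric about the domain center, the mean
        occupied-column profile over seeds is mirror-symmetric."""
        ncol, nrow = 60, 30
        x = np.abs(np.arange(ncol) - (ncol - 1) / 2)
        vals = np.tile(0.1 + 0.02 * x, (nrow, 1))
        field = SuctionField(vals, x_extent=30, y_extent=15)
        layout = PlantLayout(plant_xs=(10.0, 20.0), spacing_cm=10, taproot_depth=5.0)
        profiles = []
        for seed in range(20):
            cfg = GrowthConfig(driving=boll_exp, rng_seed=seed, kappa=2.1e-5)
            grid, _ = run_simulation(layout, field, cfg)
            profiles.append(grid.occupancy.sum(axis=0))
        mean_profile = np.mean(profiles, axis=0)
        asym = np.abs(mean_profile - mean_profile[::-1]).sum() / mean_profile.sum()
        assert asym < 0.25
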