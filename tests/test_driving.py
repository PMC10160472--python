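"""Driving laws: RLD vs suction, RWD conversions, weights and occupancy targets."""

import numpy as np
import pytest
from scipy.optimize import brentq

from rootca import (
    DRIVING_PRESETS,
    DrivingParams,
    SuctionField,
    fit_driving,
    rld_from_rwd,
    rld_from_suction,
    target_occupancy,
    weight_field,
)
from rootca.retention import DegenerateRangeError


class TestRldFromSuction:
    @pytest.mark.parametrize(
        "preset,S,expected",
        [
            ("boll-30cm", 1.0, 3373.453),  # log law at ln(1)=0 -> b
            ("boll-15cm", 0.0, 3957.418),  # exp law at S=0 -> c
            ("bud-30cm", 1.0, 1973.302),
            ("flowering-15cm", 0.0, 2834.931),
        ],
    )
    def test_printed_coefficients_at_unit_and_zero_suction(self, preset, S, expected):
        assert rld_from_suction(S, DRIVING_PRESETS[preset]) == pytest.approx(expected)

    def test_exponential_at_unit_suction_high_precision(self, boll_exp):
        # frozen from a 20-digit symbolic evaluation of c*exp(d)
        assert rld_from_suction(1.0, boll_exp) == pytest.approx(
            3072.8079719511329, rel=1e-12
        )

    def test_log_family_clamps_near_zero(self, boll_log):
        assert rld_from_suction(0.0, boll_log) == rld_from_suction(1e-3, boll_log)

    def test_decreasing_in_suction_for_all_presets(self):
        S = np.linspace(1e-3, 1.0, 200)
        for p in DRIVING_PRESETS.values():
            vals = rld_from_suction(S, p)
            assert np.all(np.diff(vals) < 0), p

    def test_family_coefficients_validated(self):
        with pytest.raises(ValueError):
            DrivingParams("logarithmic", a=-1.0)
        with pytest.raises(ValueError):
            DrivingParams("exponential", c=1.0, d=-0.1, a=2.0)


class TestFitDriving:
    def test_noiseless_log_recovery(self, boll_log):
        S = np.linspace(0.02, 1.0, 40)
        result = fit_driving(np.column_stack([S, rld_from_suction(S, boll_log)]), "logarithmic")
        assert result.params.a == pytest.approx(boll_log.a, rel=1e-3)
        assert result.params.b == pytest.approx(boll_log.b, rel=1e-3)
        assert result.r2 == pytest.approx(1.0, abs=1e-9)

    def test_perfect_exponential_r2_is_one(self, boll_exp):
        S = np.linspace(0.0, 1.0, 20)
        result = fit_driving(np.column_stack([S, rld_from_suction(S, boll_exp)]), "exponential")
        assert result.r2 == pytest.approx(1.0, abs=1e-9)

    def test_noisy_recovery_within_fifteen_percent(self, boll_exp):
        S = np.linspace(0.01, 1.0, 60)
        clean = rld_from_suction(S, boll_exp)
        errs = []
        for seed in range(20):
            rng = np.random.default_rng(seed)
            noisy = clean * (1 + 0.10 * rng.standard_normal(60))
            est = fit_driving(np.column_stack([S, noisy]), "exponential").params
            errs.append(
                max(abs(est.c - boll_exp.c) / boll_exp.c, abs(est.d - boll_exp.d) / abs(boll_exp.d))
            )
        assert np.median(errs) < 0.15

    def test_scale_equivariance(self, boll_log):
        S = np.linspace(0.05, 1.0, 30)
        rld = rld_from_suction(S, boll_log)
        base = fit_driving(np.column_stack([S, rld]), "logarithmic").params
        scaled = fit_driving(np.column_stack([S, 3.0 * rld]), "logarithmic").params
        assert scaled.a == pytest.approx(3.0 * base.a, rel=1e-6)
        assert scaled.b == pytest.approx(3.0 * base.b, rel=1e-6)

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            fit_driving([(0.5, 1.0), (0.6, 2.0)], "logarithmic")
        with pytest.raises(ValueError):
            fit_driving([(0.5, 1.0)] * 6, "exponential")


class TestRldFromRwd:
    def test_printed_coefficients_at_unit_weight(self):
        assert rld_from_rwd(1.0, "lateral") == pytest.approx(83.12)
        assert rld_from_rwd(1.0, "axis") == pytest.approx(-1685.51)

    def test_axis_zero_crossing_matches_bisection(self):
        root = brentq(lambda w: rld_from_rwd(w, "axis"), 1.0, 100.0)
        assert root == pytest.approx(np.exp(1685.51 / 831.37), rel=1e-10)
        assert rld_from_rwd(root, "axis") == pytest.approx(0.0, abs=1e-6)

    def test_nonpositive_weight_rejected(self):
        with pytest.raises(ValueError):
            rld_from_rwd(0.0, "lateral")


class TestWeightField:
    def test_uniform_field_degenerate(self, boll_log):
        field = SuctionField(np.full((20, 40), 0.5), x_extent=20, y_extent=10)
        with pytest.raises(DegenerateRangeError):
            weight_field(field, boll_log)

    def test_low_suction_half_has_larger_weights(self, boll_log):
        vals = np.full((20, 40), 0.8)
        vals[:, :20] = 0.1
        field = SuctionField(vals, x_extent=20, y_extent=10)
        w = weight_field(field, boll_log)
        assert np.all(w[:, :20] > w[:, 20:])

    def test_gamma_zero_flattens_positive_cells(self, boll_exp, small_field):
        w = weight_field(small_field, boll_exp, gamma=0.0)
        assert set(np.unique(w)) <= {0.0, 1.0}
        assert np.all(w == 1.0)  # exponential law never negative

    def test_never_negative_and_argmax_at_wettest(self, boll_log, small_field):
        w = weight_field(small_field, boll_log)
        assert np.all(w >= 0)
        assert np.unravel_index(np.argmax(w), w.shape)[1] == np.unravel_index(
            np.argmin(small_field.values), w.shape
        )[1]


class TestTargetOccupancy:
    def test_two_level_field_matches_hand_value(self, boll_log):
        # 20x20 toy: half cells at normalized suction 0 (clamped to 1e-3,
        # RLD 7021.901), half at 1 (RLD 3373.453); mean 5197.677; with
        # kappa=1e-5 the hand value is round(1e-5 * 5197.677 * 400) = 21
        vals = np.full((20, 20), 0.8)
        vals[:, :10] = 0.2
        field = SuctionField(vals, x_extent=10, y_extent=10)
        assert target_occupancy(field, boll_log, kappa=1e-5) == 21

    def test_uniform_rld_definition(self, boll_exp):
        vals = np.tile(np.linspace(0.1, 0.9, 20), (20, 1))
        field = SuctionField(vals, x_extent=10, y_extent=10)
        rld = rld_from_suction(
            (vals - vals.min()) / (vals.max() - vals.min()), boll_exp
        )
        expected = round(2e-5 * rld.mean() * 400)
        assert target_occupancy(field, boll_exp, kappa=2e-5) == expected

    def test_clipped_to_lattice_size(self, boll_log, small_field):
        with pytest.warns(UserWarning, match="clipping"):
            assert target_occupancy(small_field, boll_log, kappa=1.0) == small_field.values.size
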