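"""E_B estimation: TA-MSD, default grids, decay laws, shuffling contrasts."""

import numpy as np
import pytest

from ergocardia import (
    averages,
    compare_shuffled,
    eb_curve,
    eb_default_grid,
    generate_brownian,
    generate_fgn,
    ta_msd,
)
from ergocardia.series import InsufficientDataError, InvalidParameterError
from ergocardia.synthetic import generate_fbm


class TestAverages:
    def test_hand_examples(self):
        ens, tav = averages([[1, 3], [3, 5]], t_index=0)
        assert ens == 2.0
        _, tav = averages([[1, 2, 3]], t_index=0)
        assert tav[0] == 2.0

    def test_ergodic_iid_case(self):
        rng = np.random.default_rng(0)
        trajs = [rng.standard_normal(200) for _ in range(200)]
        ens, tav = averages(trajs, t_index=50)
        assert abs(ens - tav.mean()) < 0.2

    def test_empty_ensemble_rejected(self):
        with pytest.raises(InsufficientDataError):
            averages([], 0)


class TestTaMsd:
    def test_hand_examples(self):
        assert ta_msd([0, 1, 2, 3, 4], 2) == 4.0
        assert ta_msd(np.full(10, 3.0), 3) == 0.0
        assert ta_msd([0, 2, 1, 3], 1) == pytest.approx(3.0)

    def test_lag_must_fit(self):
        with pytest.raises(InsufficientDataError):
            ta_msd([1, 2], 2)


class TestDefaultGrid:
    def test_raw_rules(self):
        lag, grid = eb_default_grid(100_000, "raw")
        assert lag == 10
        assert grid[0] == 20 and grid[-1] == 2000

    def test_epoch_rules(self):
        lag, grid = eb_default_grid(40, "epochs")
        assert lag == 1
        assert grid[0] == 3 and grid[-1] == 20
        assert np.array_equal(grid, np.arange(3, 21))

    def test_raw_minimum_duration(self):
        _, grid = eb_default_grid(100_000, "raw")
        assert np.all(grid > 10)


class TestEbCurve:
    def test_nonnegative_and_affine_invariant(self):
        x = generate_fgn(0.7, 8192, seed=0).values
        a = eb_curve(x, 10, np.array([30, 60, 120, 240]))
        b = eb_curve(5.0 * x - 17.0, 10, np.array([30, 60, 120, 240]))
        assert np.all(a.eb_values >= 0)
        assert np.allclose(a.eb_values, b.eb_values, rtol=1e-9)

    def test_brownian_four_thirds_law(self):
        ratios = []
        for s in range(10):
            b = generate_brownian(10**5, seed=s)
            lag, grid = eb_default_grid(10**5, "raw")
            c = eb_curve(b.values, lag, grid)
            # weight toward the asymptotic regime: t >= 10 * lag
            sel = c.t_grid >= 100
            ratios.append(np.mean(c.eb_values[sel] * c.t_grid[sel] / lag))
        assert np.mean(ratios) == pytest.approx(4 / 3, rel=0.15)

    def test_iid_slope_near_minus_one(self):
        slopes = []
        for s in range(20):
            x = np.random.default_rng(s).standard_normal(10_000)
            lag, grid = eb_default_grid(10_000, "raw")
            slopes.append(eb_curve(x, lag, grid).slope_loglog)
        assert np.mean(slopes) == pytest.approx(-1.0, abs=0.15)

    def test_fbm_h09_slow_decay_regime(self):
        slopes = []
        for s in range(10):
            f = generate_fbm(0.9, 10**5, seed=s)
            lag, grid = eb_default_grid(10**5, "raw")
            slopes.append(eb_curve(f.values, lag, grid).slope_loglog)
        assert np.mean(slopes) == pytest.approx(-0.4, abs=0.15)

    def test_duration_must_exceed_lag(self):
        with pytest.raises(InvalidParameterError):
            eb_curve(np.arange(100.0), 10, np.array([5, 10]))


class TestCompareShuffled:
    def test_iid_gap_near_zero(self):
        gaps = []
        for s in range(20):
            x = np.random.default_rng(100 + s).standard_normal(5000)
            _, _, gap = compare_shuffled(x, mode="raw", seed=s)
            gaps.append(gap)
        assert abs(np.mean(gaps)) < 0.2

    def test_nonergodic_motion_positive_gap(self):
        # fBm with H=0.9 decays slowly (slope -4+4H = -0.4); shuffling its
        # values destroys the temporal structure and restores fast decay
        wins = 0
        for s in range(20):
            x = generate_fbm(0.9, 10_000, seed=200 + s).values
            _, _, gap = compare_shuffled(x, mode="raw", seed=s)
            wins += gap > 0
        assert wins >= 16  # >= 80% of seeds

    def test_shuffled_variant_labeled(self):
        x = generate_fgn(0.6, 4096, seed=5).values
        orig, shuf, _ = compare_shuffled(x, mode="raw", seed=0)
        assert orig.variant == "original" and shuf.variant == "shuffled"
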