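"""Generators: exact fGn covariance, Brownian construction, cascade mass, cohorts."""

import numpy as np
import pytest

from ergocardia import (
    CohortSpec,
    GroupSpec,
    InvalidParameterError,
    generate_binomial_cascade,
    generate_brownian,
    generate_cohort,
    generate_fgn,
    generate_rri_series,
    shuffle_series,
)
from ergocardia.dfa import dfa
from ergocardia.synthetic import binomial_cascade_alpha, fgn_autocovariance


class TestFgn:
    def test_h_half_is_white_noise(self):
        x = generate_fgn(0.5, 4096, seed=1).values
        r1 = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(r1) < 3 / np.sqrt(4096)

    def test_dfa_recovers_hurst(self):
        est = [dfa(generate_fgn(0.8, 8192, seed=s).values).hurst for s in range(20)]
        assert abs(np.mean(est) - 0.8) < 0.05

    def test_ensemble_autocovariance_matches_closed_form(self):
        # ensemble of realizations; sample autocovariance at lags 0..5
        h, n, reps = 0.7, 256, 500
        acs = np.zeros((reps, 6))
        for i in range(reps):
            x = generate_fgn(h, n, seed=10_000 + i).values
            for k in range(6):
                acs[i, k] = np.mean(x[: n - k] * x[k:])
        target = fgn_autocovariance(np.arange(6), h)
        se = acs.std(axis=0, ddof=1) / np.sqrt(reps)
        assert np.all(np.abs(acs.mean(axis=0) - target) < 3 * se + 1e-12)

    def test_prescribed_marginal_sd(self):
        x = np.concatenate(
            [generate_fgn(0.6, 1024, sd=2.5, seed=s).values for s in range(50)]
        )
        assert np.std(x) == pytest.approx(2.5, rel=0.05)

    @pytest.mark.parametrize("bad_h", [0.0, 1.0, -0.3, 1.7])
    def test_invalid_hurst_rejected(self, bad_h):
        with pytest.raises(InvalidParameterError):
            generate_fgn(bad_h, 64, seed=0)


class TestBrownian:
    def test_starts_at_zero_and_unit_increments(self):
        b = generate_brownian(10**5, seed=3).values
        assert b[0] == 0.0
        assert np.var(np.diff(b)) == pytest.approx(1.0, abs=0.02)


class TestCascade:
    def test_uniform_measure_at_p_half(self):
        c = generate_binomial_cascade(0.5, 8, seed=0).values
        assert np.allclose(c, 2.0**-8)

    @pytest.mark.parametrize("p,levels", [(0.6, 6), (0.7, 10), (0.9, 14)])
    def test_mass_conserved_and_extreme_weights(self, p, levels):
        c = generate_binomial_cascade(p, levels, seed=42).values
        assert abs(c.sum() - 1.0) < 1e-12
        # the all-heavy and all-light root-to-leaf paths always exist
        assert np.log2(c.max()) == pytest.approx(levels * np.log2(max(p, 1 - p)), rel=1e-9)
        assert np.log2(c.min()) == pytest.approx(levels * np.log2(min(p, 1 - p)), rel=1e-9)

    def test_closed_form_alpha_endpoints(self):
        # analytic oracle values for p = 0.7 over q in [-5, 5]
        assert binomial_cascade_alpha(5.0, 0.7) == pytest.approx(0.532, abs=0.001)
        assert binomial_cascade_alpha(-5.0, 0.7) == pytest.approx(1.720, abs=0.001)

    def test_out_of_range_p_rejected(self):
        with pytest.raises(InvalidParameterError):
            generate_binomial_cascade(0.4, 8, seed=0)


class TestRriSeries:
    def test_no_ectopics_all_normal(self):
        beats = generate_rri_series(length=512, ectopic_rate=0.0, seed=0)
        assert set(beats.label) == {"N"}

    def test_ectopic_labeling_and_halving(self):
        clean = generate_rri_series(length=4096, ectopic_rate=0.0, seed=5)
        dirty = generate_rri_series(length=4096, ectopic_rate=0.05, seed=5)
        ect = dirty.label == "V"
        assert 0.02 < ect.mean() < 0.08
        assert np.allclose(dirty.rr_ms[ect], clean.rr_ms[ect] / 2.0)
        assert np.allclose(dirty.rr_ms[~ect], clean.rr_ms[~ect])

    def test_times_are_cumulative_intervals(self):
        beats = generate_rri_series(length=256, seed=1)
        assert np.allclose(np.diff(beats.time_s) * 1000.0, beats.rr_ms[1:])

    def test_linear_configuration_is_gaussian(self):
        # p = 0.5 disables the cascade: the series is pure scaled fGn
        from scipy import stats

        beats = generate_rri_series(
            mean_rr=800, sd_rr=50, cascade_p=0.5, hurst=0.5, length=8192, seed=2
        )
        z = (beats.rr_ms - beats.rr_ms.mean()) / beats.rr_ms.std()
        assert abs(stats.skew(z)) < 0.1
        assert abs(stats.kurtosis(z)) < 0.2


class TestCohort:
    def test_counts_labels_and_determinism(self):
        spec = CohortSpec(
            groups=[GroupSpec(label=g, n_subjects=5, series_length=512)
                    for g in ("healthy", "survivor", "nonsurvivor")],
            seed=11,
        )
        cohort = generate_cohort(spec)
        assert len(cohort) == 15
        assert [g for g, _ in cohort] == ["healthy"] * 5 + ["survivor"] * 5 + ["nonsurvivor"] * 5
        again = generate_cohort(spec)
        for (g1, b1), (g2, b2) in zip(cohort, again):
            assert g1 == g2
            assert np.array_equal(b1.rr_ms, b2.rr_ms)
            assert np.array_equal(b1.label, b2.label)

    def test_grand_mean_near_nominal(self):
        n = 2**13
        spec = CohortSpec(
            groups=[GroupSpec(label="healthy", n_subjects=5, mean_rr=800.0,
                              sd_rr=40.0, hurst=0.5, cascade_p=0.5,
                              series_length=n)],
            seed=3,
        )
        for _, beats in generate_cohort(spec):
            assert abs(beats.rr_ms.mean() - 800.0) < 3 * 40.0 / np.sqrt(n)


class TestShuffle:
    def test_value_multiset_preserved(self, cascade_rri):
        shuffled = shuffle_series(cascade_rri, seed=0)
        assert np.array_equal(np.sort(shuffled.rr_ms), np.sort(cascade_rri.rr_ms))

    def test_destroys_long_range_correlation(self):
        est = []
        for s in range(10):
            x = generate_fgn(0.9, 4096, seed=s)
            est.append(dfa(shuffle_series(x, seed=s).values).hurst)
        assert abs(np.mean(est) - 0.5) < 0.07
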