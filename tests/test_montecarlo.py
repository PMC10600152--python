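"""Monte-Carlo specificity: segment sampling, calibration, power, monotonicity."""

import numpy as np
import pytest
from scipy import stats

from ergocardia import (
    CohortSpec,
    GroupSpec,
    generate_cohort,
    mc_specificity,
    sample_segment,
)
from ergocardia.series import InsufficientDataError, InvalidParameterError


def _null_cohort(n_per_group=4, length=2**13, seed=0, **kw):
    spec = CohortSpec(
        groups=[GroupSpec(label=g, n_subjects=n_per_group, mean_rr=800.0,
                          sd_rr=50.0, hurst=kw.get("hurst", 0.5),
                          cascade_p=0.5, series_length=length)
                for g in ("a", "b", "c")],
        seed=seed,
    )
    return generate_cohort(spec)


class TestSampleSegment:
    def test_exact_length_recording_deterministic(self):
        x = np.arange(100.0)
        seg, start = sample_segment(x, 100, seed=5)
        assert start == 0 and np.array_equal(seg, x)

    def test_fixed_seed_reproducible(self):
        x = np.arange(10_000.0)
        a, s1 = sample_segment(x, 1000, seed=7)
        b, s2 = sample_segment(x, 1000, seed=7)
        assert s1 == s2 and np.array_equal(a, b)

    def test_start_indices_uniform(self):
        x = np.zeros(100_000)
        starts = [sample_segment(x, 1000, seed=s)[1] for s in range(2000)]
        upper = 100_000 - 1000
        p = stats.kstest(np.asarray(starts) / upper, "uniform").pvalue
        assert p > 0.01

    def test_too_short_recording_rejected(self, cascade_rri):
        with pytest.raises(InsufficientDataError, match=str(len(cascade_rri))):
            sample_segment(cascade_rri, len(cascade_rri) + 1, seed=0)


class TestMcSpecificity:
    def test_single_iteration_reproducible(self):
        cohort = _null_cohort()
        a = mc_specificity(cohort, "M", n_iter=1, seg_len=500, seed=3)
        b = mc_specificity(cohort, "M", n_iter=1, seg_len=500, seed=3)
        assert np.array_equal(a.p_values, b.p_values)
        assert a.p_values.shape == (1, 3)  # anova + 2 contrasts

    def test_null_type_one_error_calibrated(self):
        cohort = _null_cohort(n_per_group=5, length=2**15, seed=1)
        result = mc_specificity(cohort, "M", n_iter=300, seg_len=1000,
                                test="anova", alpha=0.05, seed=4)
        assert result.failure_rate[0] == pytest.approx(0.95, abs=0.04)

    def test_hurst_gap_detected_by_hfgn(self):
        spec = CohortSpec(
            groups=[
                GroupSpec(label="ctrl", n_subjects=5, hurst=0.55, cascade_p=0.5,
                          series_length=2**13),
                GroupSpec(label="case", n_subjects=5, hurst=0.75, cascade_p=0.5,
                          series_length=2**13),
            ],
            seed=2,
        )
        cohort = generate_cohort(spec)
        result = mc_specificity(cohort, "H_fGn", n_iter=100, seg_len=1000,
                                test="anova", seed=5)
        assert result.failure_rate[0] < 0.10

    def test_failure_rate_monotone_in_effect_size(self):
        rates = []
        for delta in (0.0, 40.0, 120.0):
            spec = CohortSpec(
                groups=[
                    GroupSpec(label="ctrl", n_subjects=5, mean_rr=800.0, sd_rr=40.0,
                              hurst=0.5, cascade_p=0.5, series_length=2**13),
                    GroupSpec(label="case", n_subjects=5, mean_rr=800.0 - delta,
                              sd_rr=40.0, hurst=0.5, cascade_p=0.5,
                              series_length=2**13),
                ],
                seed=6,
            )
            result = mc_specificity(generate_cohort(spec), "M", n_iter=150,
                                    seg_len=1000, test="anova", seed=7)
            rates.append(result.failure_rate[0])
        assert rates[0] >= rates[1] >= rates[2]

    def test_group_and_count_validation(self):
        cohort = _null_cohort(n_per_group=2)
        with pytest.raises(InvalidParameterError):
            mc_specificity(cohort, "M", n_iter=2, seg_len=100, seed=0)
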