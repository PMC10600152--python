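"""Cleaning rules, spline resampling, and epoching conventions."""

import numpy as np
import pytest

from ergocardia import (
    BeatSeries,
    InsufficientDataError,
    UniformSeries,
    clean_rri,
    resample_rri,
    split_epochs,
)
from ergocardia.series import read_tachogram, write_tachogram


def _beats(rr, labels):
    rr = np.asarray(rr, dtype=float)
    return BeatSeries(time_s=np.cumsum(rr) / 1000.0, rr_ms=rr,
                      label=np.asarray(labels, dtype="U1"))


def _beats_from_times(times, rr):
    return BeatSeries(time_s=np.asarray(times, float),
                      rr_ms=np.asarray(rr, float),
                      label=np.full(len(rr), "N"))


class TestCleanRri:
    def test_ectopic_replaced_by_flanking_median(self):
        beats = _beats([790, 400, 810], ["N", "V", "N"])
        cleaned, report = clean_rri(beats)
        assert np.allclose(cleaned.rr_ms, [790, 800, 810])
        assert report.corrected_indices == [1]
        assert list(cleaned.label) == ["N", "N", "N"]

    def test_all_normal_is_identity(self, cascade_rri):
        cleaned, report = clean_rri(cascade_rri)
        assert np.array_equal(cleaned.rr_ms, cascade_rri.rr_ms)
        assert report.n_corrected == 0

    def test_large_jump_flagged_but_not_altered(self):
        # 25% jump flagged; 19% drop stays under the 20% threshold
        beats = _beats([800, 1000, 810], ["N", "N", "N"])
        cleaned, report = clean_rri(beats)
        assert report.flagged_indices == [1]
        assert np.array_equal(cleaned.rr_ms, beats.rr_ms)

    def test_boundary_ectopic_uses_single_neighbor(self):
        beats = _beats([400, 790, 810], ["V", "N", "N"])
        cleaned, _ = clean_rri(beats)
        assert cleaned.rr_ms[0] == 790

    def test_following_variant(self):
        beats = _beats([700, 400, 800, 900], ["N", "V", "N", "N"])
        cleaned, _ = clean_rri(beats, interpolation="following")
        assert cleaned.rr_ms[1] == 850  # median of the two next N intervals

    def test_all_ectopic_unprocessable(self):
        beats = _beats([400, 410], ["V", "V"])
        with pytest.raises(InsufficientDataError):
            clean_rri(beats)

    def test_idempotent(self):
        rng = np.random.default_rng(0)
        rr = 800 + 30 * rng.standard_normal(200)
        labels = np.where(rng.random(200) < 0.1, "V", "N")
        labels[0] = "N"
        beats = _beats(rr, labels)
        once, _ = clean_rri(beats)
        twice, report2 = clean_rri(once)
        assert report2.n_corrected == 0
        assert np.array_equal(once.rr_ms, twice.rr_ms)

    def test_times_recomputed_consistently(self, tiny_beats):
        cleaned, _ = clean_rri(tiny_beats)
        assert np.allclose(np.diff(cleaned.time_s) * 1000.0, cleaned.rr_ms[1:])


class TestResample:
    def test_constant_series_reproduced(self):
        beats = _beats([500] * 10, ["N"] * 10)
        out = resample_rri(beats)
        assert np.allclose(out.values, 500.0)

    def test_grid_spacing_500ms(self, cascade_rri):
        out = resample_rri(cascade_rri, rate_hz=2.0)
        assert np.allclose(np.diff(out.times_s), 0.5)

    def test_sample_count_inclusive_grid(self):
        # beats exactly every 500 ms for one hour -> 7201 samples at 2 Hz
        rr = np.full(7201, 500.0)
        beats = _beats(rr, ["N"] * 7201)
        out = resample_rri(beats, rate_hz=2.0)
        assert len(out) == 7201

    def test_linear_trend_reproduced_interior(self):
        # build intervals that are exactly linear in beat *time*; cubic spline
        # interpolation then reproduces the line exactly (up to end effects)
        a, b = 700.0, 1.0  # rr(t) = a + b * t  (ms, with t in s)
        times = [0.7]
        for _ in range(49):
            times.append((times[-1] + a / 1000.0) / (1.0 - b / 1000.0))
        times = np.asarray(times)
        rr = a + b * times
        beats = _beats_from_times(times, rr)
        out = resample_rri(beats)
        expected = a + b * out.times_s
        interior = slice(2, -2)
        assert np.allclose(out.values[interior], expected[interior], rtol=1e-6)

    def test_too_few_beats_rejected(self):
        with pytest.raises(InsufficientDataError):
            resample_rri(_beats([800, 810, 790], ["N"] * 3))


class TestSplitEpochs:
    @pytest.mark.parametrize("n,epoch_len,expected", [
        (10_000, 500, 20),
        (10_250, 500, 20),   # 250-beat remainder dropped
        (499, 500, 0),
    ])
    def test_epoch_counts(self, n, epoch_len, expected):
        segments = split_epochs(np.arange(n, dtype=float), epoch_len)
        assert len(segments) == expected
        # conservation: segments plus remainder account for every point
        assert sum(len(s) for s in segments) + n % epoch_len == n

    def test_uniform_epoch_spans_500s(self):
        x = UniformSeries(values=np.zeros(2000), rate_hz=2.0)
        segments = split_epochs(x, 1000)
        assert len(segments) == 2
        assert segments[1].t0_s - segments[0].t0_s == 500.0

    def test_beat_epochs_preserve_fields(self, cascade_rri):
        segments = split_epochs(cascade_rri, 500)
        assert all(len(s) == 500 for s in segments)
        assert np.array_equal(segments[0].rr_ms, cascade_rri.rr_ms[:500])


class TestTachogramIO:
    def test_round_trip(self, tmp_path, cascade_rri):
        path = tmp_path / "subj.csv"
        write_tachogram(cascade_rri, path)
        back = read_tachogram(path)
        assert np.allclose(back.rr_ms, cascade_rri.rr_ms)
        assert np.array_equal(back.label, cascade_rri.label)
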