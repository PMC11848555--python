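"""Preprocessing chain: smoothing, binning, top-hat, detection, alignment."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import ndimage

from smfkit.containers import RawSpectrum, BinnedSpectrum, PeakList
from smfkit.preprocess import (PreprocessConfig, smooth, bin_spectrum,
                               baseline_tophat, detect_peaks, align,
                               run_preprocessing)


def uniform_spectrum(intensity, start=100.0, step=0.01):
    n = len(intensity)
    return RawSpectrum(start + step * np.arange(n), np.asarray(intensity, float))


class TestSmooth:
    def test_unit_impulse_gives_gaussian_kernel(self):
        y = np.zeros(101)
        y[50] = 1.0
        out = smooth(uniform_spectrum(y), sigma=1.0)
        # discretized Gaussian: peak value ~ 1/sqrt(2 pi) = 0.3989
        assert out.intensity[50] == pytest.approx(0.3989, abs=0.01)
        assert out.intensity.sum() == pytest.approx(1.0, rel=1e-6)

    def test_constant_unchanged(self):
        out = smooth(uniform_spectrum(np.full(50, 3.0)))
        np.testing.assert_allclose(out.intensity, 3.0, rtol=1e-12)

    def test_variance_reduction_on_white_noise(self, rng):
        y = rng.uniform(0, 1, 2000) + 5.0
        out = smooth(uniform_spectrum(y))
        assert out.intensity.var() < y.var()

    def test_total_intensity_conserved(self, rng):
        y = rng.uniform(0, 100, 500)
        out = smooth(uniform_spectrum(y))
        assert out.intensity.sum() == pytest.approx(y.sum(), rel=1e-6)

    def test_nonuniform_grid_rejected(self):
        spec = RawSpectrum(np.array([1.0, 2.0, 10.0]), np.ones(3))
        with pytest.raises(ValueError, match="uniform"):
            smooth(spec)


class TestBin:
    def test_bin_count_arithmetic(self):
        spec = uniform_spectrum(np.ones(10))
        binned = bin_spectrum(spec, 0.05, (100, 600))
        assert binned.n_bins == 10_000

    def test_sum_aggregation(self):
        spec = RawSpectrum(np.array([100.01, 100.02]), np.array([3.0, 4.0]))
        binned = bin_spectrum(spec, 0.05, (100.0, 100.1))
        assert binned.intensity.tolist() == [7.0, 0.0]

    def test_exact_conservation(self, rng):
        mz = np.sort(rng.uniform(100, 600, 5000))
        mz = np.unique(mz)
        inten = rng.uniform(0, 1000, len(mz))
        spec = RawSpectrum(mz, inten)
        binned = bin_spectrum(spec, 0.05, (100, 600))
        in_range = (mz >= 100) & (mz < 600)
        assert binned.intensity.sum() == pytest.approx(
            inten[in_range].sum(), abs=1e-9 * inten.sum())

    def test_bad_width_rejected(self):
        with pytest.raises(ValueError, match="width"):
            bin_spectrum(uniform_spectrum(np.ones(5)), width=0.0)


def brute_force_opening(y, size):
    """Erosion then dilation with a flat element — direct definition."""
    n = len(y)
    half_lo = (size - 1) // 2
    half_hi = size // 2
    def window(arr, i):
        return arr[max(0, i - half_lo): min(n, i + half_hi + 1)]
    eroded = np.array([window(y, i).min() for i in range(n)])
    return np.array([window(eroded, i).max() for i in range(n)])


class TestTophat:
    def make(self, y, width=0.05):
        return BinnedSpectrum(100.0, 100.0 + width * len(y), width, np.asarray(y, float))

    def test_constant_maps_to_zero(self):
        out = baseline_tophat(self.make(np.full(100, 7.0)), element_width=1.0)
        assert np.all(out.intensity == 0)

    def test_narrow_peak_on_zero_baseline_preserved(self):
        y = np.zeros(50)
        y[20:23] = [5.0, 9.0, 4.0]
        out = baseline_tophat(self.make(y), element_width=0.5)  # 10-bin element
        np.testing.assert_allclose(out.intensity, y)

    def test_ramp_removed_peak_kept(self):
        ramp = np.linspace(0, 10, 200)
        y = ramp.copy()
        y[100] += 50.0
        out = baseline_tophat(self.make(y), element_width=1.0)  # 20 bins
        assert out.intensity[100] == pytest.approx(50.0, rel=0.05)
        off_peak = np.delete(out.intensity, [99, 100, 101])
        assert off_peak.max() <= 10 * (20 / 199) + 1e-9  # one element of ramp rise

    def test_matches_brute_force_morphology(self, rng):
        y = rng.uniform(0, 10, 50)
        size = 5
        spec = self.make(y)
        out = baseline_tophat(spec, element_width=size * 0.05)
        expected = np.clip(y - brute_force_opening(y, size), 0, None)
        np.testing.assert_allclose(out.intensity, expected)

    @settings(max_examples=25, deadline=None)
    @given(st.lists(st.floats(0, 1e4), min_size=12, max_size=60))
    def test_idempotent_and_nonnegative(self, vals):
        spec = self.make(vals)
        once = baseline_tophat(spec, element_width=0.25)
        twice = baseline_tophat(once, element_width=0.25)
        assert np.all(once.intensity >= 0)
        np.testing.assert_allclose(twice.intensity, once.intensity, atol=1e-9)

    def test_small_element_rejected(self):
        with pytest.raises(ValueError, match="3 bins"):
            baseline_tophat(self.make(np.ones(10)), element_width=0.05)


class TestDetectPeaks:
    def test_all_zero_gives_empty(self):
        spec = BinnedSpectrum(100, 105, 0.05, np.zeros(100))
        assert len(detect_peaks(spec)) == 0

    def test_single_gaussian_apex(self):
        x = np.arange(200)
        y = 100.0 * np.exp(-0.5 * ((x - 77) / 2.0) ** 2)
        spec = BinnedSpectrum(100, 110, 0.05, y)
        peaks = detect_peaks(spec)
        assert len(peaks) == 1
        assert abs(peaks.peak_mz[0] - spec.bin_centers[77]) < 0.05

    def test_planted_peak_recovery(self, raw_cohort):
        """On one rendered spectrum with 134 planted peaks at high S/N:
        recall >= 0.95 and false-discovery fraction <= 0.05."""
        _, spectra, _, truth = raw_cohort
        binned = bin_spectrum(smooth(spectra[0]), 0.05, (100, 600))
        peaks = detect_peaks(baseline_tophat(binned, 2.0))
        d_true = np.array([np.min(np.abs(peaks.peak_mz - mz))
                           for mz in truth.peak_mz])
        recall = np.mean(d_true <= 0.1)
        d_det = np.array([np.min(np.abs(truth.peak_mz - mz))
                          for mz in peaks.peak_mz])
        fdr = np.mean(d_det > 0.1)
        assert recall >= 0.95
        assert fdr <= 0.05


class TestAlign:
    def make_pl(self, mzs, intensities, sid="s"):
        return PeakList(np.asarray(mzs, float), np.asarray(intensities, float),
                        np.full(len(mzs), 10.0), sample_id=sid)

    def test_merge_within_tolerance(self):
        fm = align([self.make_pl([200.00], [5], "a"),
                    self.make_pl([200.03], [7], "b")], tolerance=0.1)
        assert fm.n_signals == 1
        assert fm.signal_mz[0] == pytest.approx(200.015)
        assert fm.values.tolist() == [[5.0], [7.0]]

    def test_split_beyond_tolerance(self):
        fm = align([self.make_pl([200.00], [5], "a"),
                    self.make_pl([200.03], [7], "b")],
                   tolerance=0.01, min_fraction=0.0)
        assert fm.n_signals == 2

    def test_min_fraction_drops_rare_signals(self):
        pls = [self.make_pl([100.0], [1], f"s{i}") for i in range(4)]
        pls[0] = self.make_pl([100.0, 300.0], [1, 9], "s0")
        fm = align(pls, tolerance=0.1, min_fraction=0.5)
        assert fm.n_signals == 1

    def test_bad_tolerance(self):
        with pytest.raises(ValueError, match="tolerance"):
            align([self.make_pl([1], [1]), self.make_pl([1], [1])], tolerance=0)

    def test_permutation_invariance(self, rng):
        pls = [self.make_pl(np.sort(rng.uniform(100, 110, 5)),
                            rng.uniform(1, 9, 5), f"s{i}") for i in range(6)]
        fm = align(pls, 0.5, min_fraction=0.0)
        order = rng.permutation(6)
        fm2 = align([pls[i] for i in order], 0.5, min_fraction=0.0)
        np.testing.assert_allclose(fm2.values, fm.values[order])
        np.testing.assert_allclose(fm2.signal_mz, fm.signal_mz)


class TestFullChain:
    def test_cohort_recovers_planted_signal_count(self, raw_cohort):
        """The chain standardizes exactly the planted 134 signal positions,
        each within half a bin of its true m/z, one row per sample."""
        cfg, spectra, _, truth = raw_cohort
        fm = run_preprocessing(spectra, PreprocessConfig(),
                               group_of_sample=truth.group_of_sample)
        assert fm.n_signals == cfg.n_peaks == 134
        assert fm.n_samples == cfg.n_case + cfg.n_control
        err = np.array([np.min(np.abs(truth.peak_mz - mz))
                        for mz in fm.signal_mz])
        assert err.max() <= 0.025
        assert not np.isnan(fm.values).any()

    def test_intensity_scaling_scales_matrix_row(self, raw_cohort):
        _, spectra, _, _ = raw_cohort
        subset = [s for s in spectra if s.sample_id in ("MMD001", "MMD002",
                                                        "HC001")]
        fm = run_preprocessing(subset, PreprocessConfig())
        scaled = [RawSpectrum(s.mz, s.intensity * (3.0 if s.sample_id == "HC001" else 1.0),
                              sample_id=s.sample_id, replicate=s.replicate,
                              batch=s.batch) for s in subset]
        fm2 = run_preprocessing(scaled, PreprocessConfig())
        i = fm.sample_ids.index("HC001")
        # compare columns matched by reference m/z (signal sets can differ
        # marginally at the detection threshold)
        for j, mz in enumerate(fm.signal_mz):
            k = np.argmin(np.abs(fm2.signal_mz - mz))
            if abs(fm2.signal_mz[k] - mz) < 0.05 and fm.values[i, j] > 0:
                np.testing.assert_allclose(fm2.values[i, k],
                                           3.0 * fm.values[i, j], rtol=0.02)

    def test_empty_input_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            run_preprocessing([], PreprocessConfig())

    def test_deterministic(self, raw_cohort):
        _, spectra, _, _ = raw_cohort
        sub = spectra[:6]
        a = run_preprocessing(sub, PreprocessConfig())
        b = run_preprocessing(sub, PreprocessConfig())
        np.testing.assert_array_equal(a.values, b.values)
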