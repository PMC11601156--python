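"""Preprocessing-stage contracts, checked against independent small oracles."""

import numpy as np
import pytest

from maldicrs.preprocess import (
    PeakList,
    align_peaklists,
    average_by_concentration,
    bin_peaks,
    detect_peaks,
    estimate_noise,
    filter_monoisotopic,
    isotope_lambda,
    normalize,
    recalibrate_to_reference,
    remove_baseline_tophat,
    smooth_savitzky_golay,
    sqrt_transform,
)
from maldicrs.spectra_io import PlateLayout, Spectrum

from conftest import gaussian_spectrum


def _spec(y, mz0=400.0, step=0.02, spot="s"):
    y = np.asarray(y, dtype=float)
    return Spectrum(mz=mz0 + step * np.arange(len(y)), intensity=y, spot_id=spot)


def _opening_oracle(y, half_window):
    """Brute-force grey opening: erosion then dilation with a flat SE."""
    n, w = len(y), half_window
    padded = np.pad(y, w, mode="edge")
    eroded = np.array([padded[i:i + 2 * w + 1].min() for i in range(n)])
    padded = np.pad(eroded, w, mode="edge")
    return np.array([padded[i:i + 2 * w + 1].max() for i in range(n)])


class TestSavitzkyGolay:
    def test_polynomials_reproduced_exactly(self):
        x = np.arange(200.0)
        const = _spec(np.full(200, 7.0))
        np.testing.assert_allclose(
            smooth_savitzky_golay(const, 10, 3).intensity, 7.0, atol=1e-9
        )
        quad = _spec(0.01 * x**2 + 0.5 * x + 3)
        np.testing.assert_allclose(
            smooth_savitzky_golay(quad, 10, 3).intensity, quad.intensity, atol=1e-9
        )

    def test_reduces_white_noise_variance(self):
        rng = np.random.default_rng(0)
        y = 10 + rng.normal(0, 1, 5000)
        out = smooth_savitzky_golay(_spec(y), 10, 3)
        assert np.var(out.intensity) < np.var(y)

    def test_window_must_exceed_spectrum(self):
        with pytest.raises(ValueError):
            smooth_savitzky_golay(_spec(np.ones(15)), 10, 3)

    def test_double_application_blocked(self):
        s = smooth_savitzky_golay(_spec(np.ones(100)), 5, 2)
        with pytest.raises(ValueError, match="already applied"):
            smooth_savitzky_golay(s, 5, 2)


class TestTopHat:
    def test_narrow_peak_on_flat_baseline(self):
        y = np.full(200, 5.0)
        y[100] = 15.0
        out = remove_baseline_tophat(_spec(y), half_window=10)
        assert out.intensity[100] == pytest.approx(10.0)
        np.testing.assert_allclose(np.delete(out.intensity, 100), 0.0, atol=1e-12)

    def test_all_zero_stays_zero(self):
        out = remove_baseline_tophat(_spec(np.zeros(100)), half_window=5)
        np.testing.assert_array_equal(out.intensity, 0.0)

    def test_matches_brute_force_morphology_oracle(self):
        rng = np.random.default_rng(3)
        y = np.abs(rng.normal(2, 1, 300)) + np.linspace(0, 5, 300)
        out = remove_baseline_tophat(_spec(y), half_window=7)
        np.testing.assert_allclose(out.intensity, y - _opening_oracle(y, 7), atol=1e-12)

    def test_ramp_removed_within_edge_effects(self):
        y = np.linspace(0.0, 10.0, 400)
        out = remove_baseline_tophat(_spec(y), half_window=50)
        assert np.all(out.intensity[:-101] <= y.max() * 0.3)

    def test_output_bounded_by_input_and_zero(self):
        rng = np.random.default_rng(1)
        y = np.abs(rng.normal(0, 1, 500)) + 3 * np.sin(np.arange(500) / 40) ** 2
        out = remove_baseline_tophat(_spec(y), half_window=20)
        assert np.all(out.intensity <= y + 1e-12)
        assert np.all(out.intensity >= 0)


class TestSqrtTransform:
    def test_elementwise_square_root(self):
        out = sqrt_transform(_spec([0.0, 1.0, 4.0, 9.0]))
        np.testing.assert_array_equal(out.intensity, [0.0, 1.0, 2.0, 3.0])

    def test_single_application_enforced(self):
        s = sqrt_transform(_spec([1.0, 4.0]))
        with pytest.raises(ValueError, match="already applied"):
            sqrt_transform(s)

    def test_stabilizes_poisson_variance(self):
        """sqrt of Poisson(mean 100) counts has variance ≈ 1/4."""
        rng = np.random.default_rng(7)
        counts = rng.poisson(100, size=100_000).astype(float)
        out = sqrt_transform(_spec(counts))
        assert np.var(out.intensity) == pytest.approx(0.25, rel=0.2)


class TestNoiseEstimate:
    def test_constant_spectrum_is_noiseless(self):
        assert estimate_noise(_spec(np.full(50, 3.0))) == 0.0

    def test_calibrated_on_standard_normal(self):
        rng = np.random.default_rng(11)
        y = rng.normal(0, 1, 100_000)
        # shift into the valid non-negative range; MAD is shift-invariant
        s = Spectrum(mz=np.arange(len(y), dtype=float),
                     intensity=y - y.min(), spot_id="n")
        assert estimate_noise(s) == pytest.approx(1.0, rel=0.02)

    def test_robust_to_single_spike(self):
        rng = np.random.default_rng(13)
        y = 10 + rng.normal(0, 0.5, 1001)
        base = estimate_noise(_spec(y))
        y_spiked = y.copy()
        y_spiked[500] = 1e6
        assert estimate_noise(_spec(y_spiked)) == pytest.approx(base, rel=0.01)


class TestDetectPeaks:
    def test_single_gaussian_found_at_apex(self):
        s = gaussian_spectrum(peaks=((420.0, 50.0),), noise_sd=1.0, seed=2)
        pl = detect_peaks(s, snr_threshold=3.0, half_window=10)
        strong = pl.mz[pl.intensity > 25]
        assert len(strong) == 1
        assert strong[0] == pytest.approx(420.0, abs=0.05)

    @pytest.mark.parametrize("seed", range(5))
    def test_pure_noise_yields_no_peaks_at_high_threshold(self, seed):
        s = gaussian_spectrum(peaks=(), noise_sd=1.0, baseline=10.0, seed=seed)
        pl = detect_peaks(s, snr_threshold=10.0, half_window=10)
        assert len(pl) == 0

    def test_two_separated_gaussians(self):
        s = gaussian_spectrum(peaks=((420.0, 50.0), (430.0, 40.0)), noise_sd=1.0, seed=4)
        pl = detect_peaks(s, snr_threshold=3.0, half_window=10)
        strong = pl.mz[pl.intensity > 20]
        assert len(strong) == 2

    def test_apex_interpolation_beats_grid_quantization(self):
        # true apex placed between grid points
        s = gaussian_spectrum(peaks=((420.007, 50.0),))
        pl = detect_peaks(s, snr_threshold=3.0, half_window=10)
        assert abs(pl.mz[np.argmax(pl.intensity)] - 420.007) < 0.005


class TestMonoisotopicFilter:
    def _pl(self, mzs, ints):
        return PeakList("s", np.asarray(mzs), np.asarray(ints),
                        np.full(len(mzs), 10.0))

    def test_a1_satellite_collapsed(self):
        """At mass 760 the Poisson model expects A+1/A ≈ 0.42, so an observed
        0.45 ratio marks 761.6 as the isotope of 760.6."""
        assert isotope_lambda(760.6) == pytest.approx(0.42, abs=0.01)
        out = filter_monoisotopic(self._pl([760.6, 761.6], [1.0, 0.45]), tol_ppm=500)
        np.testing.assert_array_equal(out.mz, [760.6])

    def test_singleton_kept(self):
        out = filter_monoisotopic(self._pl([500.0], [1.0]))
        np.testing.assert_array_equal(out.mz, [500.0])

    def test_descending_envelope_collapsed_to_head(self):
        lam = isotope_lambda(500.0)
        assert 0.25 * lam <= 0.3 <= 4 * lam          # A+1 oracle consistency
        assert 0.25 * lam**2 / 2 <= 0.05 <= 4 * lam**2 / 2
        out = filter_monoisotopic(
            self._pl([500.0, 501.0, 502.0], [1.0, 0.3, 0.05]), tol_ppm=500
        )
        np.testing.assert_array_equal(out.mz, [500.0])

    def test_inconsistent_ratio_not_absorbed(self):
        # a second peak far too intense to be an isotope satellite
        out = filter_monoisotopic(self._pl([500.0, 501.0], [1.0, 3.0]), tol_ppm=500)
        assert len(out) == 2

    def test_gap_tolerated_for_a2(self):
        lam = isotope_lambda(800.0)
        out = filter_monoisotopic(
            self._pl([800.0, 802.0047], [1.0, lam**2 / 2]), tol_ppm=500
        )
        np.testing.assert_array_equal(out.mz, [800.0])


class TestRecalibration:
    def _peaks(self, mzs, ints):
        return PeakList("s", np.asarray(mzs), np.asarray(ints),
                        np.full(len(mzs), 10.0))

    def test_constant_shift_applied(self):
        s = _spec(np.ones(100), mz0=854.0)
        out = recalibrate_to_reference(s, self._peaks([854.08], [5.0]), 854.10, tol=0.1)
        assert out.metadata["recalibration_shift"] == pytest.approx(0.02)
        np.testing.assert_allclose(out.mz, s.mz + 0.02)

    def test_exact_match_zero_shift(self):
        s = _spec(np.ones(100), mz0=854.0)
        out = recalibrate_to_reference(s, self._peaks([854.10], [5.0]), 854.10, tol=0.1)
        assert out.metadata["recalibration_shift"] == 0.0

    def test_missing_reference_flags_for_qc(self):
        s = _spec(np.ones(100), mz0=854.0)
        with pytest.warns(UserWarning, match="not recalibrated"):
            out = recalibrate_to_reference(s, self._peaks([850.0], [5.0]), 854.10, tol=0.1)
        assert out.metadata["recalibration_failed"]
        np.testing.assert_array_equal(out.mz, s.mz)


class TestNormalize:
    def test_tic_sums_to_one(self):
        out = normalize(_spec([1.0, 3.0]), "tic")
        np.testing.assert_allclose(out.intensity, [0.25, 0.75])
        assert out.metadata["normalization_factor"] == 4.0

    def test_internal_standard_scaling(self):
        y = np.zeros(100)
        y[50] = 10.0
        y[10] = 2.0
        s = _spec(y, mz0=400.0)
        out = normalize(s, "internal_standard", ref_mz=s.mz[50], tol=0.1)
        assert out.intensity[10] == pytest.approx(0.2)

    def test_tic_is_scale_invariant(self):
        rng = np.random.default_rng(5)
        y = rng.uniform(0, 1, 50)
        a = normalize(_spec(y), "tic")
        b = normalize(_spec(7.3 * y), "tic")
        np.testing.assert_allclose(a.intensity, b.intensity)

    def test_zero_divisor_identifies_spot(self):
        with pytest.raises(ValueError, match="spot"):
            normalize(_spec(np.zeros(10), spot="badspot"), "tic")


class TestAlignment:
    def _pl(self, mzs, spot):
        mzs = np.asarray(mzs, dtype=float)
        return PeakList(spot, mzs, np.ones(len(mzs)), np.full(len(mzs), 10.0))

    def test_identity_warp_for_identical_lists(self):
        base = [400.0, 450.0, 500.0, 550.0]
        out = align_peaklists([self._pl(base, f"s{i}") for i in range(4)], tol_ppm=200)
        for pl in out:
            a, b = pl.metadata["warp"]
            assert a == pytest.approx(1.0, abs=1e-9)
            assert b == pytest.approx(0.0, abs=1e-6)

    def test_recovers_constant_shift(self):
        base = np.array([400.0, 450.0, 500.0, 550.0])
        lists = [self._pl(base, f"s{i}") for i in range(4)]
        lists.append(self._pl(base + 0.05, "shifted"))
        out = align_peaklists(lists, tol_ppm=200)
        a, b = out[-1].metadata["warp"]
        assert a == pytest.approx(1.0, abs=1e-6)
        assert b == pytest.approx(-0.05, abs=1e-6)
        np.testing.assert_allclose(out[-1].mz, base, atol=1e-6)

    def test_unmatched_spot_flagged(self):
        base = [400.0, 450.0, 500.0, 550.0]
        lists = [self._pl(base, f"s{i}") for i in range(3)] + [self._pl([700.0], "lost")]
        with pytest.warns(UserWarning, match="unwarped"):
            out = align_peaklists(lists, tol_ppm=200)
        assert out[-1].metadata["alignment_failed"]


class TestBinning:
    def _pl(self, mzs, ints, spot):
        return PeakList(spot, np.asarray(mzs, float), np.asarray(ints, float),
                        np.full(len(mzs), 10.0))

    def test_coincident_peaks_form_one_feature(self):
        lists = [
            self._pl([349.10 * (1 + s * 1e-6)], [2.0], f"s{s}") for s in range(4)
        ]
        m = bin_peaks(lists, tol_ppm=50)
        assert len(m.feature_mz) == 1
        assert np.count_nonzero(m.values) == 4

    def test_gap_beyond_tolerance_splits(self):
        lists = [self._pl([349.10, 349.30], [1.0, 1.0], "a"),
                 self._pl([349.10, 349.30], [1.0, 1.0], "b")]
        m = bin_peaks(lists, tol_ppm=50)
        assert len(m.feature_mz) == 2

    def test_missing_peak_yields_zero_without_spectra(self):
        lists = [self._pl([349.10], [2.0], "a"), self._pl([], [], "b")]
        m = bin_peaks(lists, tol_ppm=50)
        assert m.values[0, 0] == 2.0
        assert m.values[0, 1] == 0.0

    def test_missing_peak_filled_from_spectrum_when_given(self):
        lists = [self._pl([420.0], [5.0], "a"), self._pl([], [], "b")]
        spectra = [gaussian_spectrum(peaks=((420.0, 3.0),))]
        spectra[0] = spectra[0].replace(spot_id="b")
        m = bin_peaks(lists, tol_ppm=50, spectra=spectra)
        assert m.values[0, 1] == pytest.approx(3.0, rel=0.01)

    def test_spot_permutation_leaves_features_unchanged(self):
        rng = np.random.default_rng(9)
        lists = [
            self._pl(np.sort(rng.uniform(400, 500, 5)), rng.uniform(1, 3, 5), f"s{i}")
            for i in range(6)
        ]
        m1 = bin_peaks(lists, tol_ppm=100)
        m2 = bin_peaks(lists[::-1], tol_ppm=100)
        np.testing.assert_allclose(m1.feature_mz, m2.feature_mz)


class TestAverageByConcentration:
    def _matrix(self, values, concs):
        import pandas as pd

        spots = [f"s{i}" for i in range(len(concs))]
        layout = PlateLayout(pd.DataFrame({
            "spot_id": spots, "concentration": concs,
            "replicate_index": 1, "compound_id": "c",
        }))
        from maldicrs.preprocess import IntensityMatrix

        return IntensityMatrix(np.array([500.0]), spots,
                               np.asarray(values, float)[None, :], layout)

    def test_mean_and_sample_sd(self):
        m = self._matrix([1.0, 2.0, 3.0, 4.0], [1e-6] * 4)
        concs, means, sds, counts = average_by_concentration(m)
        assert means[0, 0] == pytest.approx(2.5)
        assert sds[0, 0] == pytest.approx(1.2909944, rel=1e-6)

    def test_single_replicate_sd_zero_and_counted(self):
        m = self._matrix([5.0], [1e-6])
        concs, means, sds, counts = average_by_concentration(m)
        assert means[0, 0] == 5.0
        assert sds[0, 0] == 0.0
        assert counts[0] == 1

    def test_excluded_outlier_leaves_mean_and_sd(self):
        m = self._matrix([1.0, 2.0, 3.0, 100.0], [1e-6] * 4)
        concs, means, sds, _ = average_by_concentration(m, exclude_spots=("s3",))
        assert means[0, 0] == pytest.approx(2.0)
        assert sds[0, 0] == pytest.approx(1.0)

    def test_fully_excluded_group_is_an_error(self):
        m = self._matrix([1.0, 2.0], [1e-6, 1e-5])
        with pytest.raises(ValueError, match="excluded"):
            average_by_concentration(m, exclude_spots=("s1",))

    def test_columns_ordered_by_concentration(self):
        m = self._matrix([3.0, 1.0, 2.0], [1e-4, 1e-6, 1e-5])
        concs, means, _, _ = average_by_concentration(m)
        np.testing.assert_allclose(concs, [1e-6, 1e-5, 1e-4])
        np.testing.assert_allclose(means[0], [1.0, 2.0, 3.0])
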