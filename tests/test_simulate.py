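"""Surrogates, synthetic noise, activation shapes and the pseudoreal mixture."""

import numpy as np
import pytest
import scipy.stats

from localcca import (
    fourier_resample,
    injected_amplitudes,
    make_activation_timecourse,
    mix_pseudoreal,
    mix_timecourses,
    peak_snr_percent,
    random_activation_shape,
    simulate_patch,
    simulate_pseudoreal_slice,
    synthetic_resting_noise,
)
from localcca.errors import InvalidInputError, InvalidParameterError


class TestFourierResample:
    def test_amplitude_spectrum_preserved(self, rng):
        x = rng.standard_normal((64, 5))
        s = fourier_resample(x, seed=1).data
        assert np.allclose(
            np.abs(np.fft.rfft(s, axis=0)), np.abs(np.fft.rfft(x, axis=0)), atol=1e-8
        )

    def test_mean_preserved(self, rng):
        x = rng.normal(3.0, 1.0, (50, 4))
        s = fourier_resample(x, seed=2).data
        assert np.allclose(s.mean(axis=0), x.mean(axis=0), atol=1e-10)

    def test_perfectly_correlated_voxels_stay_correlated(self, rng):
        """The shared phase vector preserves inter-voxel phase differences."""
        a = rng.standard_normal(80)
        x = np.column_stack([a, 2.0 * a + 1.0])
        s = fourier_resample(x, seed=3).data
        assert np.corrcoef(s.T)[0, 1] == pytest.approx(1.0, abs=1e-10)

    def test_output_is_real_for_even_and_odd_lengths(self, rng):
        for n in (64, 65):
            s = fourier_resample(rng.standard_normal((n, 2)), seed=4).data
            assert s.shape == (n, 2)
            assert np.isrealobj(s)

    def test_ar1_autocorrelation_preserved_in_expectation(self):
        """Spectrum preservation keeps the lag-1 autocorrelation on average."""
        rng = np.random.default_rng(11)
        n = 400
        x = synthetic_resting_noise((1, 1), n, spatial_fwhm=0.0, ar_coeff=0.6,
                                    seed=rng)[0, 0]
        def lag1(v):
            return np.corrcoef(v[:-1], v[1:])[0, 1]
        acs = [lag1(fourier_resample(x, seed=rng).data) for _ in range(200)]
        assert abs(np.mean(acs) - lag1(x)) < 0.05

    def test_phase_randomization_destroys_alignment(self):
        rng = np.random.default_rng(21)
        x = synthetic_resting_noise((1, 1), 256, ar_coeff=0.4, seed=rng)[0, 0]
        corrs = [
            np.corrcoef(x, fourier_resample(x, seed=rng).data)[0, 1]
            for _ in range(300)
        ]
        assert abs(np.mean(corrs)) < 0.05

    def test_short_series_rejected(self, rng):
        with pytest.raises(InvalidInputError):
            fourier_resample(rng.standard_normal((4, 2)), seed=0)


class TestSyntheticNoise:
    def test_unit_variance_and_shape(self, rng):
        x = synthetic_resting_noise((5, 4), 100, seed=rng)
        assert x.shape == (5, 4, 100)
        assert np.allclose(x.std(axis=-1), 1.0, atol=1e-10)
        assert np.allclose(x.mean(axis=-1), 0.0, atol=1e-12)

    def test_white_limit(self):
        x = synthetic_resting_noise((2, 2), 2000, spatial_fwhm=0.0, ar_coeff=0.0,
                                    seed=5)
        flat = x.reshape(4, -1)
        lag1 = np.mean([np.corrcoef(v[:-1], v[1:])[0, 1] for v in flat])
        cross = np.corrcoef(flat)[np.triu_indices(4, 1)]
        assert abs(lag1) < 0.05
        assert np.abs(cross).max() < 0.08

    def test_fwhm_two_gives_strong_neighbor_correlation(self):
        x = synthetic_resting_noise((20, 20), 300, spatial_fwhm=2.0, seed=6)
        pairs = [
            np.corrcoef(x[i, j], x[i, j + 1])[0, 1]
            for i in range(20)
            for j in range(19)
        ]
        assert np.mean(pairs) > 0.3

    def test_seed_reproducibility(self):
        a = synthetic_resting_noise((3, 3), 50, seed=7)
        b = synthetic_resting_noise((3, 3), 50, seed=7)
        assert np.array_equal(a, b)

    def test_invalid_ar_rejected(self):
        with pytest.raises(InvalidParameterError):
            synthetic_resting_noise((2, 2), 50, ar_coeff=1.0)


class TestActivationTimecourse:
    def test_single_regressor_normalized_copy(self, small_X):
        x = make_activation_timecourse(small_X, [1.0, 0.0, 0.0, 0.0])
        ref = small_X.X[:, 0] / small_X.X[:, 0].std()
        assert np.allclose(x, ref)

    def test_unit_variance_always(self, small_X, rng):
        for _ in range(10):
            x = make_activation_timecourse(small_X, rng.uniform(0, 1, 4))
            assert x.std() == pytest.approx(1.0, abs=1e-12)

    def test_amplitude_scale_drops_out(self, small_X):
        a = make_activation_timecourse(small_X, [1.0, 0.0, 0.0, 0.0])
        b = make_activation_timecourse(small_X, [2.0, 0.0, 0.0, 0.0])
        assert np.allclose(a, b)

    def test_all_zero_rejected(self, small_X):
        with pytest.raises(InvalidInputError):
            make_activation_timecourse(small_X, np.zeros(4))


class TestMixture:
    def test_pure_null_and_pure_signal_limits(self, rng):
        x_act = rng.standard_normal(50)
        noise = rng.standard_normal((3, 3, 50))
        active = np.zeros((3, 3), dtype=bool)
        active[1, 1] = True
        pure_null = mix_pseudoreal(x_act, noise, active, f=1.0)
        assert np.allclose(pure_null, noise)
        pure_sig = mix_pseudoreal(x_act, noise, active, f=0.0)
        assert np.allclose(pure_sig[1, 1], x_act)
        assert np.allclose(pure_sig[0, 0], noise[0, 0])

    def test_invalid_fraction_rejected(self, rng):
        with pytest.raises(InvalidParameterError):
            mix_timecourses(rng.standard_normal(10), rng.standard_normal(10), 1.2)

    def test_peak_snr_regimes(self):
        assert round(peak_snr_percent(0.55)) == 67
        assert round(peak_snr_percent(0.65)) == 29

    def test_truth_labels_exact_by_construction(self, small_X, rng):
        shape = random_activation_shape(rng)
        data, truth = simulate_patch(small_X, 0.5, [0.5, 0.5, 0.5, 0.5], shape,
                                     seed=rng)
        assert truth.sum() == shape.K
        assert truth[1, 1]

    def test_injected_amplitudes_scale(self, small_X):
        amps = np.array([1.0, 0.0, 0.0, 0.0])
        inj = injected_amplitudes(small_X, amps, f=0.5)
        assert inj[0] == pytest.approx(0.5 / small_X.X[:, 0].std())
        assert np.allclose(inj[1:], 0.0)


class TestActivationShapes:
    def test_center_always_active(self, rng):
        for _ in range(200):
            assert (0, 0) in random_activation_shape(rng).offsets

    def test_sizes_uniform_on_two_to_nine(self):
        rng = np.random.default_rng(31)
        sizes = np.array([random_activation_shape(rng).K for _ in range(100_000)])
        counts = np.bincount(sizes, minlength=10)[2:10]
        _, p = scipy.stats.chisquare(counts)
        assert p > 0.01

    def test_seeded_reproducibility(self):
        assert (
            random_activation_shape(3).offsets == random_activation_shape(3).offsets
        )


class TestPseudorealSlice:
    def test_focal_slice_truth_and_shapes(self, small_X):
        data, truth = simulate_pseudoreal_slice(
            small_X, 0.6, slice_shape=(16, 16), mode="focal", n_clusters=4, seed=0
        )
        assert data.shape == (16, 16, small_X.n)
        assert 0 < truth.sum() <= 4 * 9

    def test_extended_slice_is_one_disc(self, small_X):
        _, truth = simulate_pseudoreal_slice(
            small_X, 0.6, slice_shape=(16, 16), mode="extended", seed=0
        )
        from scipy.ndimage import label

        _, n_components = label(truth)
        assert n_components == 1
        assert truth.sum() > 20

    def test_contrast_positive_amplitudes(self, small_X):
        c = np.array([0.0, 1.0, 0.0, -1.0])
        data, truth = simulate_pseudoreal_slice(
            small_X, 0.3, slice_shape=(12, 12), mode="focal", contrast=c, seed=1
        )
        # strong-signal voxels should show a positive contrast effect on average
        from localcca import Contrast, classical_t

        ts = [
            classical_t(small_X, data[i, j], Contrast(c))[0]
            for i, j in zip(*np.nonzero(truth))
        ]
        assert np.mean(ts) > 0.0
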