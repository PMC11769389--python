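"""Oracle-checked tests for the six per-channel feature extractors."""

import numpy as np
import pytest
import pywt
from scipy.integrate import quad

import soilnose as sn
from conftest import kinetic_profile

C = sn.N_CHANNELS


def _signal(matrix_1d):
    """Broadcast a 1-D time series to all 26 channels."""
    return np.tile(np.asarray(matrix_1d, dtype=float)[:, None], (1, C))


def _random_response(n=256, seed=0):
    return np.random.default_rng(seed).normal(0, 1, (n, C))


class TestAveMaxIV:
    def test_constant_signal(self):
        resp = np.full((50, C), 2.0)
        assert np.allclose(sn.extract_ave(resp), 2.0)
        assert np.allclose(sn.extract_max(resp), 2.0)
        # trapezoid on a constant: value x duration (N-1)/fs
        iv = sn.extract_iv(np.full((6000, C), 2.0), 100.0)
        assert np.allclose(iv, 2.0 * 59.99)

    def test_linear_ramp_integral_exact(self):
        ramp = _signal(np.linspace(0.0, 1.0, 6000))
        assert np.allclose(sn.extract_iv(ramp, 100.0), 29.995)

    def test_kinetic_curve_mean_matches_analytic_average(self):
        # time-average of b + A(1 - e^{-t/tau}) over [0, T]
        b, A, tau, fs, n = 0.1, 1.0, 5.0, 100.0, 6000
        prof = kinetic_profile(baseline=b, amplitude=A, rise_time_s=tau)
        resp = sn.simulate_response(prof, 1.0, 0.0, n, fs, np.random.default_rng())
        T = (n - 1) / fs
        analytic = b + A * (1 - (tau / T) * (1 - np.exp(-T / tau)))
        assert np.allclose(sn.extract_ave(resp), analytic, rtol=1e-3)

    def test_kinetic_curve_integral_matches_quadrature_oracle(self):
        b, A, tau, fs, n = 0.1, 1.0, 5.0, 100.0, 6000
        prof = kinetic_profile(baseline=b, amplitude=A, rise_time_s=tau)
        resp = sn.simulate_response(prof, 1.0, 0.0, n, fs, np.random.default_rng())
        T = (n - 1) / fs
        oracle, _ = quad(lambda t: b + A * (1 - np.exp(-t / tau)), 0, T)
        assert np.allclose(sn.extract_iv(resp, fs), oracle, rtol=1e-5)

    def test_max_dominated_by_injected_spike(self):
        resp = np.full((100, C), 1.0)
        resp[37] = 9.9
        assert np.allclose(sn.extract_max(resp), 9.9)

    def test_monotone_curve_max_at_final_point(self):
        prof = kinetic_profile()
        resp = sn.simulate_response(prof, 1.0, 0.0, 500, 100.0, np.random.default_rng())
        assert np.allclose(sn.extract_max(resp), resp[-1])

    def test_iv_linearity(self):
        a = _random_response(seed=1)
        b = _random_response(seed=2)
        lhs = sn.extract_iv(a + b, 100.0)
        rhs = sn.extract_iv(a, 100.0) + sn.extract_iv(b, 100.0)
        assert np.allclose(lhs, rhs)

    def test_empty_matrix_is_shape_error(self):
        with pytest.raises(ValueError, match="time point"):
            sn.extract_ave(np.empty((0, C)))
        with pytest.raises(ValueError, match="time point"):
            sn.extract_iv(np.ones((1, C)), 100.0)


class TestFFT:
    def test_constant_is_dc_only(self):
        spec = sn.FeatureSpec("FFT", fft_n_coeffs=8)
        block = sn.extract_fft(np.full((128, C), 3.5), spec)
        assert np.allclose(block[0], 3.5)
        assert np.allclose(block[1:], 0.0, atol=1e-12)

    def test_pure_cosine_magnitude_matches_direct_dft(self):
        n, k, amp = 256, 5, 3.0
        x = amp * np.cos(2 * np.pi * k * np.arange(n) / n)
        resp = _signal(x)
        spec = sn.FeatureSpec("FFT", fft_n_coeffs=8)
        block = sn.extract_fft(resp, spec)
        # independent oracle: direct DFT sum
        dft = np.array(
            [abs(np.sum(x * np.exp(-2j * np.pi * b * np.arange(n) / n)) / n)
             for b in range(8)]
        )
        assert np.allclose(block[:, 0], dft, atol=1e-10)
        assert block[k, 0] == pytest.approx(1.5)
        others = np.delete(block[:, 0], k)
        assert np.allclose(others, 0.0, atol=1e-10)

    def test_bin0_equals_ave_on_random_signals(self):
        resp = _random_response(seed=3)
        spec = sn.FeatureSpec("FFT", fft_n_coeffs=4)
        assert np.allclose(sn.extract_fft(resp, spec)[0], sn.extract_ave(resp))

    def test_too_many_coefficients_rejected(self):
        spec = sn.FeatureSpec("FFT", fft_n_coeffs=100)
        with pytest.raises(ValueError, match="fft_n_coeffs"):
            sn.extract_fft(np.ones((16, C)), spec)


class TestPCF:
    def test_degree0_equals_mean(self):
        resp = _random_response(seed=4)
        spec = sn.FeatureSpec("PCF", poly_degree=0)
        coeffs = sn.extract_pcf(resp, spec)
        assert np.allclose(coeffs[0], sn.extract_ave(resp))

    def test_exact_polynomial_recovered(self):
        t = np.linspace(0, 1, 200)
        resp = _signal(1 + 2 * t - 3 * t**2)
        spec = sn.FeatureSpec("PCF", poly_degree=2)
        coeffs = sn.extract_pcf(resp, spec)
        assert np.allclose(coeffs[:, 0], [1.0, 2.0, -3.0], atol=1e-8)

    def test_noisy_slope_within_3_standard_errors(self):
        n, slope, noise = 6000, 2.0, 0.05
        t = np.linspace(0, 1, n)
        rng = np.random.default_rng(5)
        resp = _signal(slope * t) + rng.normal(0, noise, (n, C))
        spec = sn.FeatureSpec("PCF", poly_degree=1)
        est = sn.extract_pcf(resp, spec)[1]
        # oracle: least-squares covariance of the slope coefficient
        V = np.vander(t, 2, increasing=True)
        cov = noise**2 * np.linalg.inv(V.T @ V)
        se = np.sqrt(cov[1, 1])
        # 26 independent channel fits with a fixed seed: mean within 3 SE of
        # the channel-mean estimator, each channel within 4 SE individually
        assert abs(est.mean() - slope) < 3 * se / np.sqrt(C)
        assert np.all(np.abs(est - slope) < 4 * se)

    def test_degree_exceeding_points_rejected(self):
        spec = sn.FeatureSpec("PCF", poly_degree=5)
        with pytest.raises(ValueError, match="poly_degree"):
            sn.extract_pcf(np.ones((4, C)), spec)


class TestWT:
    def test_constant_signal_details_vanish(self):
        x = np.full(512, 4.0)
        coeffs = pywt.wavedec(x, "db4", level=3, mode="periodization")
        for det in coeffs[1:]:
            assert np.allclose(det, 0.0, atol=1e-10)
        spec = sn.FeatureSpec("WT", wavelet_level=3)
        approx = sn.extract_wt(_signal(x), spec)
        # approximation carries all the (constant) energy
        assert np.allclose(np.sum(approx[:, 0] ** 2), np.sum(x**2), rtol=1e-10)

    def test_perfect_reconstruction(self):
        resp = _random_response(n=512, seed=6)
        spec = sn.FeatureSpec("WT", wavelet_level=4)
        coeffs = pywt.wavedec(resp, "db4", level=4, axis=0, mode="periodization")
        approx = sn.extract_wt(resp, spec)
        assert np.allclose(approx, coeffs[0])  # extractor = approximation band
        recon = pywt.waverec(coeffs, "db4", axis=0, mode="periodization")
        assert np.allclose(recon, resp, atol=1e-8)

    def test_parseval_identity(self):
        resp = _random_response(n=512, seed=7)
        coeffs = pywt.wavedec(resp, "db4", level=4, axis=0, mode="periodization")
        energy = sum(np.sum(c**2) for c in coeffs)
        assert np.allclose(energy, np.sum(resp**2), rtol=1e-6)

    def test_infeasible_level_states_maximum(self):
        spec = sn.FeatureSpec("WT", wavelet_level=9)
        with pytest.raises(ValueError, match="maximum level"):
            sn.extract_wt(np.ones((64, C)), spec)


class TestFeaturizeDataset:
    @pytest.mark.parametrize(
        "method,block",
        [("Ave", 1), ("Max", 1), ("IV", 1), ("FFT", 8), ("PCF", 6), ("WT", 8)],
    )
    def test_table_shape_follows_block_arithmetic(self, small_dataset, method, block):
        spec = sn.FeatureSpec(method)
        table = sn.featurize_dataset(small_dataset, spec)
        assert table.shape == (len(small_dataset), 3 + 26 * block)
        assert list(table.columns[:3]) == ["record_id", "class_id", "condition"]

    def test_deterministic_tables(self, small_dataset):
        spec = sn.FeatureSpec("FFT")
        a = sn.featurize_dataset(small_dataset, spec)
        b = sn.featurize_dataset(small_dataset, spec)
        assert a.equals(b)

    def test_heterogeneous_shapes_rejected(self, small_dataset):
        bad = sn.LabeledDataset(
            small_dataset.records[:2]
            + [
                sn.SensorArrayRecord(
                    record_id="odd",
                    response=np.ones((7, C)),
                    sampling_rate_hz=100.0,
                    class_id="healthy",
                    condition="healthy",
                )
            ]
        )
        with pytest.raises(ValueError, match="odd"):
            sn.featurize_dataset(bad, sn.FeatureSpec("Ave"))

    def test_permutation_equivariance_in_channels(self):
        rng = np.random.default_rng(8)
        resp = rng.normal(0, 1, (256, C))
        perm = rng.permutation(C)
        rec = lambda r: sn.SensorArrayRecord(
            "x", r, 100.0, "healthy", "healthy"
        )
        for method in sn.FEATURE_METHODS:
            spec = sn.FeatureSpec(method, wavelet_level=3)
            fv = sn.featurize_record(rec(resp), spec)
            fv_p = sn.featurize_record(rec(resp[:, perm]), spec)
            size = len(fv.values) // C
            blocks = fv.values.reshape(C, size)
            blocks_p = fv_p.values.reshape(C, size)
            assert np.allclose(blocks_p, blocks[perm])

    def test_default_dimensionality_ordering(self):
        # FFT and PCF defaults are high-dimensional relative to Ave/IV/Max
        n_points = 6000
        dims = {
            m: 26 * sn.features.block_size(sn.FeatureSpec(m), n_points)
            for m in sn.FEATURE_METHODS
        }
        for high in ("FFT", "PCF"):
            for low in ("Ave", "IV", "Max"):
                assert dims[high] > dims[low]

    def test_empty_dataset_gives_empty_table(self):
        table = sn.featurize_dataset(sn.LabeledDataset([]), sn.FeatureSpec("Ave"))
        assert len(table) == 0

    def test_max_ge_ave_ge_min_per_channel(self, small_dataset):
        for rec in small_dataset.records[:5]:
            ave = sn.extract_ave(rec.response)
            mx = sn.extract_max(rec.response)
            mn = rec.response.min(axis=0)
            assert np.all(mx >= ave) and np.all(ave >= mn)
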