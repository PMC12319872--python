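import numpy as np
import pytest
from scipy.signal import get_window

from mindprobe import (FREQS, BANDS, RawSpectrum, band_range, fit_aperiodic,
                       periodic_component, session_mean_matrix, welch_psd)
from mindprobe.preprocess import Epoch
from mindprobe.spectral import SpectralMatrix

FS = 256.0


def epoch_from_core(core):
    data = np.pad(core, ((0, 0), (256, 256)), mode="reflect")
    return Epoch(data, 0.0, FS, 0, 0, "task")


def oracle_welch(core):
    """Independent brute-force estimator: mean of Hamming-windowed
    periodograms over 1-s segments stepped by 0.5 s, direct DFT."""
    w = get_window("hamming", 256)
    scale = FS * np.sum(w ** 2)
    segs = [core[:, k * 128:k * 128 + 256] for k in range(3)]
    ps = []
    for s in segs:
        X = np.fft.rfft(s * w, axis=1)
        p = 2.0 * np.abs(X) ** 2 / scale
        ps.append(p)
    p = np.mean(ps, axis=0)
    f = np.fft.rfftfreq(256, 1 / FS)
    sel = np.searchsorted(f, FREQS)
    return p[:, sel]


class TestWelch:
    def test_matches_direct_dft_oracle(self):
        rng = np.random.default_rng(0)
        core = rng.standard_normal((32, 512))
        spec = welch_psd(epoch_from_core(core))
        expected = oracle_welch(core)
        rel = np.abs(spec.power - expected) / expected
        assert rel.max() < 1e-6

    def test_sinusoid_peaks_at_its_frequency(self):
        t = np.arange(512) / FS
        core = np.tile(np.sin(2 * np.pi * 10.0 * t), (32, 1))
        spec = welch_psd(epoch_from_core(core))
        assert np.all(FREQS[spec.power.argmax(axis=1)] == 10.0)

    def test_output_shape_is_32_by_27(self):
        rng = np.random.default_rng(1)
        spec = welch_psd(epoch_from_core(rng.standard_normal((32, 512))))
        assert spec.power.shape == (32, 27)
        assert spec.power.size == 864

    def test_wrong_core_length_rejected(self):
        bad = Epoch(np.zeros((32, 800)), 0.0, FS, 0, 0, "task")
        with pytest.raises(ValueError):
            welch_psd(bad)

    def test_unbiased_for_white_noise(self):
        """Mean over many epochs of a flat-spectrum input is flat."""
        rng = np.random.default_rng(2)
        n = 4000  # epochs, batched through the channel axis
        acc = np.zeros(27)
        for _ in range(n // 32):
            core = rng.standard_normal((32, 512))
            acc += welch_psd(epoch_from_core(core)).power.sum(axis=0)
        mean = acc / n
        assert np.abs(mean / mean.mean() - 1).max() < 0.05


class TestAperiodicFit:
    def test_exact_power_law_recovered(self):
        p = 10 ** 2 * FREQS ** -1.5
        fit = fit_aperiodic(RawSpectrum(np.tile(p, (32, 1))))
        np.testing.assert_allclose(fit.offset, 2.0, atol=1e-6)
        np.testing.assert_allclose(fit.exponent, 1.5, atol=1e-6)

    def test_flat_spectrum_zero_exponent(self):
        fit = fit_aperiodic(RawSpectrum(np.full((32, 27), 3.0)))
        np.testing.assert_allclose(fit.exponent, 0.0, atol=1e-9)

    def test_planted_peak_does_not_derail_fit(self):
        """Grid-search oracle: the robust fit matches the best (offset,
        exponent) under its own trimmed loss within +-0.1."""
        peak = 0.5 * np.exp(-(FREQS - 10) ** 2 / (2 * 1.5 ** 2))
        logp = 1.0 - 1.0 * np.log10(FREQS) + peak
        fit = fit_aperiodic(RawSpectrum(10 ** logp[None, :]))
        # oracle: brute-force search minimizing the below-line residual mass
        logf = np.log10(FREQS)
        best = None
        for off in np.linspace(0.5, 1.5, 101):
            for ex in np.linspace(0.5, 1.5, 101):
                resid = logp - (off - ex * logf)
                loss = np.sum(np.minimum(resid, 0.05) ** 2)
                if best is None or loss < best[0]:
                    best = (loss, off, ex)
        assert abs(fit.exponent[0] - best[2]) < 0.1

    def test_nonpositive_power_rejected(self):
        with pytest.raises(ValueError):
            fit_aperiodic(RawSpectrum(np.zeros((2, 27))))


class TestPeriodicComponent:
    def test_peakless_power_law_gives_zero_residuals(self):
        p = 10 ** 1.2 * FREQS ** -0.8
        spec = RawSpectrum(np.tile(p, (32, 1)))
        mat = periodic_component(spec, fit_aperiodic(spec))
        assert np.abs(mat.periodic).max() < 1e-6

    def test_planted_peak_dominates_residual(self):
        peak = 0.4 * np.exp(-(FREQS - 10) ** 2 / (2 * 1.0 ** 2))
        p = 10 ** (1.0 - 1.0 * np.log10(FREQS) + peak)
        spec = RawSpectrum(np.tile(p, (4, 1)))
        mat = periodic_component(spec, fit_aperiodic(spec))
        assert np.all(FREQS[mat.periodic.argmax(axis=1)] == 10.0)

    def test_adding_aperiodic_back_reproduces_log_power(self):
        rng = np.random.default_rng(3)
        p = 10 ** rng.uniform(-1, 1, size=(32, 27))
        spec = RawSpectrum(p)
        fit = fit_aperiodic(spec)
        mat = periodic_component(spec, fit)
        logf = np.log10(FREQS)
        back = mat.periodic + (fit.offset[:, None] - fit.exponent[:, None] * logf)
        np.testing.assert_allclose(back, np.log10(p), atol=1e-12)


class TestBands:
    @pytest.mark.parametrize("name,expected", [
        ("high alpha", (10, 13)),
        ("low_theta", (4, 5)),
        ("high_beta", (21, 30)),
    ])
    def test_named_ranges(self, name, expected):
        assert band_range(name) == expected

    def test_bands_tile_grid_without_overlap(self):
        covered = []
        for lo, hi in BANDS.values():
            covered.extend(range(lo, hi + 1))
        assert sorted(covered) == list(range(4, 31))

    def test_unknown_band_rejected(self):
        with pytest.raises(KeyError):
            band_range("gamma")


class TestSessionMean:
    def test_single_matrix_identity(self):
        m = SpectralMatrix(np.arange(864.).reshape(32, 27))
        out = session_mean_matrix([m])
        np.testing.assert_array_equal(out.periodic, m.periodic)

    def test_opposite_matrices_cancel(self):
        a = np.random.default_rng(4).standard_normal((32, 27))
        out = session_mean_matrix([SpectralMatrix(a), SpectralMatrix(-a)])
        np.testing.assert_allclose(out.periodic, 0.0, atol=1e-15)

    def test_matches_direct_mean(self):
        rng = np.random.default_rng(5)
        mats = [SpectralMatrix(rng.standard_normal((32, 27)))
                for _ in range(100)]
        out = session_mean_matrix(mats)
        oracle = np.mean([m.periodic for m in mats], axis=0)
        np.testing.assert_allclose(out.periodic, oracle, atol=1e-12)

    def test_empty_list_rejected(self):
        with pytest.raises(ValueError):
            session_mean_matrix([])
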