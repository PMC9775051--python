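"""Reconvolution decay fitting: forward model and parameter recovery."""

import numpy as np
import pytest

from tdfshift.decay import (
    DecayCurve,
    DecayModel,
    convolve_model,
    fit_decay,
    fit_decays_global,
    model_decay_noiseless,
)

DT = 0.02
N_CH = 2048


def delta_irf(channel: int = 0) -> DecayCurve:
    counts = np.zeros(N_CH)
    counts[channel] = 1.0
    return DecayCurve(counts=counts, channel_width=DT)


def gaussian_irf(fwhm: float = 0.1, t0: float = 1.0, peak: float = 1e4) -> DecayCurve:
    t = (np.arange(N_CH) + 0.5) * DT
    sigma = fwhm / (2 * np.sqrt(2 * np.log(2)))
    return DecayCurve(counts=peak * np.exp(-0.5 * ((t - t0) / sigma) ** 2), channel_width=DT)


class TestConvolveModel:
    def test_delta_irf_reproduces_pure_exponential(self):
        model = convolve_model(delta_irf(0), [100.0], [2.0])
        t = (np.arange(N_CH) + 0.5) * DT
        assert np.allclose(model, 100.0 * np.exp(-t / 2.0), rtol=1e-10)

    def test_total_counts_identity(self):
        """sum(model) = sum_j alpha_j tau_j / dt + baseline*n for a
        contained decay (midpoint quadrature, tolerance 0.1%)."""
        model = convolve_model(gaussian_irf(), [500.0, 80.0], [2.0, 0.5], baseline=1.5)
        expected = (500.0 * 2.0 + 80.0 * 0.5) / DT + 1.5 * N_CH
        assert model.sum() == pytest.approx(expected, rel=1e-3)

    def test_one_channel_shift_translates_delta_irf(self):
        base = convolve_model(delta_irf(10), [100.0], [1.0])
        shifted = convolve_model(delta_irf(10), [100.0], [1.0], shift=DT)
        assert np.allclose(shifted[1:], base[:-1], rtol=1e-9)

    def test_grid_mismatch_rejected(self):
        decay = DecayCurve(counts=np.ones(100) * 20, channel_width=DT)
        with pytest.raises(ValueError, match="channel"):
            DecayModel(decay, gaussian_irf())

    def test_nonpositive_lifetime_rejected(self):
        with pytest.raises(ValueError, match="positive"):
            convolve_model(delta_irf(), [1.0], [-0.5])


class TestModelDecayNoiseless:
    def test_time_zero_is_amplitude_sum(self):
        fit = fit_decay(
            DecayCurve(convolve_model(gaussian_irf(), [800.0], [2.0]), DT),
            gaussian_irf(),
            n_components=1,
        )
        assert model_decay_noiseless(fit, [0.0])[0] == pytest.approx(
            fit.amplitudes.sum(), rel=1e-12
        )

    def test_monotone_decreasing_for_positive_amplitudes(self):
        fit = fit_decay(
            DecayCurve(convolve_model(gaussian_irf(), [800.0], [2.0]), DT),
            gaussian_irf(),
            n_components=1,
        )
        grid = np.linspace(0, 20, 200)
        assert np.all(np.diff(model_decay_noiseless(fit, grid)) < 0)


class TestFitDecay:
    def test_single_exponential_recovery(self):
        """tau = 2.0 ns, Gaussian IRF FWHM 0.1 ns, peak 1e4: within 2%."""
        irf = gaussian_irf()
        expect = convolve_model(irf, [1.0], [2.0])
        expect *= 1e4 / expect.max()
        counts = np.random.default_rng(42).poisson(expect)
        fit = fit_decay(DecayCurve(counts, DT), irf, n_components=1)
        assert fit.lifetimes[0] == pytest.approx(2.0, rel=0.02)
        # Pearson chi2 with unit-floor weights under-counts empty tail
        # channels, so values somewhat below 1 are expected
        assert 0.2 < fit.chi2_reduced < 1.3

    def test_two_exponential_recovery(self):
        """tau = 0.5, 3.0 ns with equal integral fractions: both within 10%."""
        irf = gaussian_irf()
        expect = convolve_model(irf, [6.0, 1.0], [0.5, 3.0])  # alpha*tau equal
        expect *= 1e4 / expect.max()
        counts = np.random.default_rng(43).poisson(expect)
        fit = fit_decay(DecayCurve(counts, DT), irf, n_components=2)
        assert fit.lifetimes[0] == pytest.approx(0.5, rel=0.10)
        assert fit.lifetimes[1] == pytest.approx(3.0, rel=0.10)

    def test_noiseless_self_consistency(self):
        """Refit of a model's own curve: parameters within 0.1%, chi2 << 1."""
        irf = gaussian_irf()
        curve = convolve_model(irf, [5000.0, 2000.0], [0.7, 3.2], baseline=2.0)
        fit = fit_decay(DecayCurve(curve, DT), irf, n_components=2)
        assert fit.chi2_reduced < 1e-4
        assert fit.lifetimes[0] == pytest.approx(0.7, rel=1e-3)
        assert fit.lifetimes[1] == pytest.approx(3.2, rel=1e-3)
        assert fit.amplitudes[0] == pytest.approx(5000.0, rel=1e-3)

    def test_median_recovery_over_replicates(self):
        """20 seeded replicates at peak 1e4: median |tau error| <= 2%."""
        irf = gaussian_irf()
        expect = convolve_model(irf, [1.0], [2.0])
        expect *= 1e4 / expect.max()
        errs = []
        for seed in range(20):
            counts = np.random.default_rng(seed).poisson(expect)
            fit = fit_decay(DecayCurve(counts, DT), irf, n_components=1)
            errs.append(abs(fit.lifetimes[0] - 2.0) / 2.0)
        assert np.median(errs) <= 0.02

    def test_rescaling_leaves_lifetimes_unchanged(self):
        irf = gaussian_irf()
        curve = convolve_model(irf, [3000.0, 800.0], [0.8, 3.0])
        f1 = fit_decay(DecayCurve(curve, DT), irf, n_components=2)
        f10 = fit_decay(DecayCurve(curve * 10, DT), irf, n_components=2)
        assert np.allclose(f10.lifetimes, f1.lifetimes, rtol=1e-3)
        assert np.allclose(f10.amplitudes, 10 * f1.amplitudes, rtol=1e-2)

    def test_redundant_component_does_not_degrade_chi2(self):
        irf = gaussian_irf()
        expect = convolve_model(irf, [1.0], [2.0])
        expect *= 1e4 / expect.max()
        counts = np.random.default_rng(44).poisson(expect)
        c1 = fit_decay(DecayCurve(counts, DT), irf, n_components=1).chi2_reduced
        c2 = fit_decay(DecayCurve(counts, DT), irf, n_components=2).chi2_reduced
        assert c2 <= c1 + 0.05

    def test_covariance_and_summary(self):
        irf = gaussian_irf()
        counts = np.random.default_rng(45).poisson(
            convolve_model(irf, [8000.0], [2.0])
        )
        fit = fit_decay(DecayCurve(counts, DT), irf, n_components=1)
        assert fit.covariance is not None
        assert fit.covariance.shape == (len(fit.param_names),) * 2
        # 1-sigma on tau should be tiny at ~1e6 photons
        i = fit.param_names.index("tau0")
        assert 0 < np.sqrt(fit.covariance[i, i]) < 0.02
        assert "chi2_reduced" in fit.summary()

    def test_low_counts_rejected(self):
        irf = gaussian_irf()
        with pytest.raises(ValueError, match="1000"):
            DecayModel(DecayCurve(np.ones(N_CH) * 0.1, DT), irf)

    def test_component_count_validated(self):
        irf = gaussian_irf()
        decay = DecayCurve(convolve_model(irf, [1e3], [2.0]), DT)
        with pytest.raises(ValueError, match="n_components"):
            DecayModel(decay, irf, n_components=5)


class TestGlobalFit:
    def test_shared_lifetimes_recovered(self):
        irf = gaussian_irf()
        curves = [
            DecayCurve(convolve_model(irf, a, [0.6, 3.0]), DT, wavelength=w)
            for a, w in [([5000.0, 300.0], 440.0), ([500.0, 2000.0], 500.0)]
        ]
        result = fit_decays_global(curves, irf, n_components=2)
        assert result.lifetimes[0] == pytest.approx(0.6, rel=1e-3)
        assert result.lifetimes[1] == pytest.approx(3.0, rel=1e-3)
        assert result.amplitudes[0][0] == pytest.approx(5000.0, rel=1e-2)
        assert len(result.fits) == 2
        assert result.fits[1].decay.wavelength == 500.0
        assert "Global" in result.summary()

    def test_mismatched_grids_rejected(self):
        irf = gaussian_irf()
        with pytest.raises(ValueError, match="channel grid"):
            fit_decays_global([DecayCurve(np.ones(64) * 100, DT)], irf)
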