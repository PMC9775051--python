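"""Headline TDFS observables: nu(0), nu(inf), delta_nu, tau_r."""

import numpy as np
import pytest

from tdfshift import Spectrum
from tdfshift.lineshape import LogNormalShape, lognormal_eval
from tdfshift.metrics import (
    SolvationResponse,
    SpectralRelaxationModel,
    estimate_time_zero,
    extrapolate_nu_inf,
    overall_shift,
    relaxation_time,
)


def exp_series(nu_inf=21000.0, amps=(3000.0,), taus=(1.0,), t=None):
    if t is None:
        t = np.geomspace(0.002, 20.0, 80)
    nu = np.full_like(t, nu_inf)
    for a, tau in zip(amps, taus):
        nu = nu + a * np.exp(-t / tau)
    return t, nu


class TestExtrapolateNuInf:
    def test_exact_single_exponential(self):
        t, nu = exp_series()
        result = extrapolate_nu_inf(t, nu)
        assert result.nu_inf == pytest.approx(21000.0, abs=1.0)
        assert result.delta_nu == pytest.approx(3000.0, rel=1e-3)

    def test_two_component_series(self):
        t, nu = exp_series(amps=(1500.0, 1500.0), taus=(0.6, 2.4))
        result = extrapolate_nu_inf(t, nu)
        assert result.nu_inf == pytest.approx(21000.0, abs=2.0)
        assert result.tau_r == pytest.approx(1.5, rel=1e-2)

    def test_truncated_series_flags_incomplete_relaxation(self):
        t = np.linspace(0.01, 1.0, 30)  # window = 1 x tau
        _, nu = exp_series(taus=(1.0,), t=t)
        with pytest.warns(UserWarning, match="incomplete"):
            result = extrapolate_nu_inf(t, nu)
        assert result.incomplete_relaxation

    def test_constant_series_rejected(self):
        t = np.geomspace(0.01, 10, 20)
        with pytest.raises(ValueError, match="no net red shift"):
            SpectralRelaxationModel(t, np.full_like(t, 21000.0))

    def test_too_few_points_rejected(self):
        with pytest.raises(ValueError, match=">= 6"):
            SpectralRelaxationModel([0.1, 0.2, 0.3], [3.0, 2.0, 1.0])

    def test_summary_reports_observables(self):
        t, nu = exp_series()
        s = extrapolate_nu_inf(t, nu).summary()
        assert "tau_r" in s and "delta_nu" in s


class TestOverallShift:
    def test_simple_difference(self):
        assert overall_shift(25000.0, 22000.0) == 3000.0

    def test_null_response_flagged(self):
        with pytest.warns(UserWarning, match="null"):
            assert overall_shift(22000.0, 22000.0) == 0.0

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError):
            overall_shift(np.nan, 22000.0)


class TestRelaxationTime:
    def test_single_component_is_its_lifetime(self):
        t, nu = exp_series(taus=(1.0,))
        result = extrapolate_nu_inf(t, nu)
        tau = relaxation_time(result)
        assert tau.analytic == pytest.approx(1.0, rel=1e-6)
        assert tau.numeric == pytest.approx(1.0, rel=0.01)

    def test_two_components_amplitude_weighted(self):
        t, nu = exp_series(amps=(1500.0, 1500.0), taus=(1.0, 3.0), t=np.geomspace(0.002, 30, 120))
        result = extrapolate_nu_inf(t, nu)
        assert relaxation_time(result).analytic == pytest.approx(2.0, rel=1e-3)

    def test_invariant_under_common_additive_shift(self):
        t, nu = exp_series()
        r1 = extrapolate_nu_inf(t, nu)
        r2 = extrapolate_nu_inf(t, nu + 500.0)
        assert relaxation_time(r2).analytic == pytest.approx(
            relaxation_time(r1).analytic, rel=1e-6
        )

    def test_discrepant_paths_warn(self):
        t, nu = exp_series()
        result = extrapolate_nu_inf(t, nu)
        result.nu = nu + 300.0 * np.sin(t)  # corrupt the observed series
        with pytest.warns(UserWarning, match="disagree"):
            relaxation_time(result)

    def test_correlation_function_normalised(self):
        t, nu = exp_series()
        result = extrapolate_nu_inf(t, nu)
        c = result.correlation()
        assert c[0] == pytest.approx(1.0, abs=5e-3)
        assert np.all((c > -1e-9) & (c < 1 + 1e-6))


def lognormal_spectrum(nu_p, lam_lo, lam_hi):
    wl = np.linspace(lam_lo, lam_hi, 200)
    nu = 1e7 / wl
    shape = LogNormalShape(h=1.0, nu_p=nu_p, delta=3500.0, gamma=-0.2)
    # per-wavelength intensities: include the Jacobian the reader inverts
    return Spectrum(wavelength=wl, intensity=lognormal_eval(shape, nu) * 1e7 / wl**2)


class TestEstimateTimeZero:
    def test_identical_polar_and_reference_absorption(self):
        absorption = lognormal_spectrum(27000.0, 300.0, 480.0)
        emission = lognormal_spectrum(23000.0, 340.0, 580.0)
        nu0 = estimate_time_zero(absorption, absorption, emission)
        assert nu0 == pytest.approx(23000.0, abs=5.0)

    def test_known_stokes_difference(self):
        """abs 27000, reference Stokes shift 4000 -> nu(0) = 23000."""
        abs_polar = lognormal_spectrum(27000.0, 300.0, 480.0)
        abs_ref = lognormal_spectrum(26500.0, 300.0, 490.0)
        em_ref = lognormal_spectrum(22500.0, 350.0, 600.0)
        nu0 = estimate_time_zero(abs_polar, abs_ref, em_ref)
        assert nu0 == pytest.approx(27000.0 - 4000.0, abs=10.0)

    def test_common_reference_shift_cancels(self):
        abs_polar = lognormal_spectrum(27000.0, 300.0, 480.0)
        nu0_a = estimate_time_zero(
            abs_polar,
            lognormal_spectrum(26000.0, 300.0, 500.0),
            lognormal_spectrum(22000.0, 350.0, 620.0),
        )
        nu0_b = estimate_time_zero(
            abs_polar,
            lognormal_spectrum(26500.0, 300.0, 490.0),
            lognormal_spectrum(22500.0, 350.0, 600.0),
        )
        assert nu0_a == pytest.approx(nu0_b, abs=15.0)

    def test_edge_peaked_spectrum_rejected(self):
        wl = np.linspace(430.0, 520.0, 60)
        rising = Spectrum(wavelength=wl, intensity=np.linspace(0.1, 1.0, 60))
        ok = lognormal_spectrum(23000.0, 340.0, 580.0)
        with pytest.raises(ValueError, match="edge"):
            estimate_time_zero(rising, ok, ok)


class TestSolvationResponse:
    def test_fit_shortcut_matches_module_function(self):
        t, nu = exp_series()
        resp = SolvationResponse(times=t, nu=nu)
        assert resp.fit().nu_inf == pytest.approx(
            extrapolate_nu_inf(t, nu).nu_inf, abs=1e-6
        )

    def test_shape_mismatch_rejected(self):
        with pytest.raises(ValueError, match="matching"):
            SolvationResponse(times=np.arange(5.0), nu=np.arange(4.0))


class TestBootstrap:
    def test_parametric_bootstrap_gives_finite_spread(self, dataset):
        """Amplitude-level resampling over the fit covariances yields a
        nonzero, finite uncertainty for both observables."""
        from tdfshift import fit_decays_global
        from tdfshift.metrics import bootstrap_uncertainty

        result = fit_decays_global(dataset.decays, dataset.irf, n_components=4)
        out = bootstrap_uncertainty(
            result.fits, dataset.steady_state, n_boot=8, seed=5
        )
        assert out["n_effective"] >= 6
        assert np.isfinite(out["delta_nu_std"]) and out["delta_nu_std"] > 0
        assert np.isfinite(out["tau_r_std"]) and out["tau_r_std"] > 0
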