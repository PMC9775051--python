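"""TDFS headline observables from the spectral-relaxation series nu(t).

The time course of the emission maximum is modelled as

    nu(t) = nu_inf + (nu0 - nu_inf) * sum_i a_i exp(-t / tau_i),  sum a_i = 1,

from which the two observables follow:

    overall dynamic Stokes shift   delta_nu = nu(0) - nu(inf)      (hydration)
    integral relaxation time       tau_r = int_0^inf [nu(t) - nu(inf)] / delta_nu dt
                                         = sum_i a_i tau_i          (mobility)

nu(inf) is obtained by extrapolating nu(t) to t -> inf (the fitted
offset); nu(0) either from the fit's t=0 limit or from a time-zero
estimate built from absorption/emission spectra in a nonpolar reference
solvent, which captures relaxation faster than the instrument response.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import lmfit
import numpy as np

from .lineshape import fit_lognormal
from .tres import Spectrum

__all__ = [
    "SolvationResponse",
    "SpectralRelaxationModel",
    "SpectralRelaxationResult",
    "RelaxationTime",
    "estimate_time_zero",
    "extrapolate_nu_inf",
    "overall_shift",
    "relaxation_time",
    "bootstrap_uncertainty",
]


@dataclass
class SolvationResponse:
    """Measured nu(t) series (cm^-1 vs ns) with per-point uncertainties."""

    times: np.ndarray
    nu: np.ndarray
    nu_err: np.ndarray | None = None
    flags: np.ndarray | None = None  # per-point quality flags (e.g. edge peaks)
    nu_argmax: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.nu = np.asarray(self.nu, dtype=float)
        if self.times.shape != self.nu.shape:
            raise ValueError("times and nu must have matching shapes")

    def fit(self, max_components: int = 3, **kwargs) -> "SpectralRelaxationResult":
        return SpectralRelaxationModel(self.times, self.nu, sigma=self.nu_err, **kwargs).fit(
            max_components=max_components
        )

    def plot(self, ax=None, result: "SpectralRelaxationResult | None" = None):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        err = None
        if self.nu_err is not None and np.all(np.isfinite(self.nu_err)):
            err = self.nu_err
        ax.errorbar(self.times, self.nu, yerr=err, fmt="o", ms=3, label=r"$\nu(t)$")
        if result is not None:
            tt = np.geomspace(max(self.times[0], 1e-4), self.times[-1], 300)
            ax.plot(tt, result.predict(tt), "-", label="fit")
            ax.axhline(result.nu_inf, ls="--", color="gray", label=r"$\nu(\infty)$")
        ax.set_xscale("log")
        ax.set_xlabel("time (ns)")
        ax.set_ylabel(r"$\nu$ (cm$^{-1}$)")
        ax.legend()
        return ax


class SpectralRelaxationModel:
    """Offset + multi-exponential model for the nu(t) series.

    The component count (1..max_components) is chosen by the Akaike
    criterion; initialisation is deterministic (offset from the series
    tail, lifetimes log-spaced around the empirical 1/e time), so a rerun
    on the same series reproduces the same fit.
    """

    def __init__(self, times, nu, sigma=None) -> None:
        t = np.asarray(times, dtype=float)
        y = np.asarray(nu, dtype=float)
        if t.size != y.size or t.size < 6:
            raise ValueError("need >= 6 (time, nu) points to extrapolate nu(inf)")
        if np.any(np.diff(t) <= 0):
            raise ValueError("times must be strictly increasing")
        if y[0] <= y[-1]:
            raise ValueError(
                "nu(t) shows no net red shift (non-decreasing series): nothing to extrapolate"
            )
        self.times = t
        self.nu = y
        if sigma is not None:
            sigma = np.asarray(sigma, dtype=float)
            if not np.all(np.isfinite(sigma)) or np.any(sigma <= 0):
                sigma = None  # unusable uncertainties -> unweighted fit
        self.sigma = sigma

    def _empirical_tau(self) -> float:
        y0, y_inf = self.nu[0], self.nu[-1]
        target = y_inf + (y0 - y_inf) / np.e
        below = np.nonzero(self.nu <= target)[0]
        tau = self.times[below[0]] if below.size else self.times[-1] / 3.0
        return float(np.clip(tau, self.times[0], self.times[-1]))

    def _fit_n(self, n: int):
        t, y = self.times, self.nu
        tau_char = self._empirical_tau()
        c0 = float(y[-1])
        amp0 = float(y[0] - c0)
        taus0 = [tau_char] if n == 1 else list(np.geomspace(tau_char / 4.0, tau_char * 4.0, n))
        span = float(y.max() - y.min())
        params = lmfit.Parameters()
        # the plateau cannot sit far below the observed series, and a
        # component much slower than the window is indistinguishable from
        # the offset — both bounds block that degeneracy
        params.add("c", value=c0, min=y.min() - span, max=y.max())
        for i in range(n):
            params.add(f"A{i}", value=amp0 / n, min=0.0, max=2.0 * span)
            params.add(f"tau{i}", value=taus0[i], min=t[0] / 10.0, max=t[-1] * 3.0)

        w = 1.0 / self.sigma if self.sigma is not None else np.ones_like(y)

        def residual(p):
            v = p.valuesdict()
            model = np.full_like(t, v["c"])
            for i in range(n):
                model = model + v[f"A{i}"] * np.exp(-t / v[f"tau{i}"])
            return (y - model) * w

        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            return lmfit.minimize(residual, params, method="least_squares")

    def fit(
        self, max_components: int = 3, tail_tolerance: float = 0.01
    ) -> "SpectralRelaxationResult":
        best, best_n = None, 0
        for n in range(1, max_components + 1):
            try:
                out = self._fit_n(n)
            except Exception:
                continue
            if best is None or out.aic < best.aic - 1e-9:
                best, best_n = out, n
        if best is None:
            raise RuntimeError("nu(t) extrapolation failed for every component count")
        v = best.params.valuesdict()
        amps = np.array([v[f"A{i}"] for i in range(best_n)])
        taus = np.array([v[f"tau{i}"] for i in range(best_n)])
        order = np.argsort(taus)
        amps, taus = amps[order], taus[order]
        nu_inf = float(v["c"])
        nu_inf_err = float(best.params["c"].stderr or np.nan) if best.errorbars else float("nan")
        total = float(amps.sum())
        # relaxation still unfinished at the window end?
        remaining = float(np.sum(amps * np.exp(-self.times[-1] / taus)))
        incomplete = total > 0 and remaining > tail_tolerance * total
        if incomplete:
            warnings.warn(
                "incomplete relaxation: nu(t) has not plateaued inside the time window; "
                "nu(inf) is an extrapolation",
                stacklevel=2,
            )
        return SpectralRelaxationResult(
            times=self.times,
            nu=self.nu,
            nu_inf=nu_inf,
            nu_inf_err=nu_inf_err,
            amplitudes=amps,
            lifetimes=taus,
            n_components=best_n,
            chi2_reduced=float(best.redchi),
            aic=float(best.aic),
            incomplete_relaxation=bool(incomplete),
        )


@dataclass
class SpectralRelaxationResult:
    """Fitted nu(t) = nu_inf + sum_i A_i exp(-t/tau_i) and derived observables."""

    times: np.ndarray = field(repr=False)
    nu: np.ndarray = field(repr=False)
    nu_inf: float = 0.0
    nu_inf_err: float = float("nan")
    amplitudes: np.ndarray = field(default_factory=lambda: np.array([]))  # cm^-1
    lifetimes: np.ndarray = field(default_factory=lambda: np.array([]))  # ns, ascending
    n_components: int = 0
    chi2_reduced: float = float("nan")
    aic: float = float("nan")
    incomplete_relaxation: bool = False

    @property
    def nu0(self) -> float:
        """t=0 limit of the fitted series, cm^-1."""
        return self.nu_inf + float(self.amplitudes.sum())

    @property
    def delta_nu(self) -> float:
        """Overall dynamic Stokes shift nu(0) - nu(inf), cm^-1."""
        return float(self.amplitudes.sum())

    @property
    def components(self) -> list[tuple[float, float]]:
        """Normalised (a_i, tau_i) with sum a_i = 1."""
        total = self.amplitudes.sum()
        return [(float(a / total), float(tau)) for a, tau in zip(self.amplitudes, self.lifetimes)]

    @property
    def tau_r(self) -> float:
        """Integral relaxation time sum a_i tau_i, ns (analytic path)."""
        total = self.amplitudes.sum()
        if total <= 0:
            raise ValueError("delta_nu <= 0: relaxation time undefined")
        return float(np.sum(self.amplitudes * self.lifetimes) / total)

    def predict(self, t) -> np.ndarray:
        t = np.asarray(t, dtype=float)
        out = np.full_like(t, self.nu_inf)
        for a, tau in zip(self.amplitudes, self.lifetimes):
            out = out + a * np.exp(-t / tau)
        return out

    def correlation(self, t=None) -> np.ndarray:
        """Normalised response C(t) = (nu(t) - nu_inf) / delta_nu of the data series."""
        nu = self.nu if t is None else self.predict(t)
        return (nu - self.nu_inf) / self.delta_nu

    def summary(self) -> str:
        lines = [
            "Spectral relaxation nu(t) fit",
            "=============================",
            f"components            : {self.n_components}",
            f"nu(0)   [fit, cm^-1]  : {self.nu0:9.1f}",
            f"nu(inf)      [cm^-1]  : {self.nu_inf:9.1f} ± {self.nu_inf_err:.1f}",
            f"delta_nu     [cm^-1]  : {self.delta_nu:9.1f}",
            f"tau_r           [ns]  : {self.tau_r:9.3f}",
            f"chi2_reduced          : {self.chi2_reduced:.4g}",
            f"incomplete relaxation : {self.incomplete_relaxation}",
            "  i        a_i        tau_i (ns)",
        ]
        for i, (a, tau) in enumerate(self.components):
            lines.append(f"  {i}  {a:9.4f}  {tau:12.4g}")
        return "\n".join(lines)


def extrapolate_nu_inf(times, nu, sigma=None, max_components: int = 3) -> SpectralRelaxationResult:
    """Extrapolate nu(t) for t -> inf: weighted offset + multi-exponential fit.

    The offset is nu(inf); the component count is chosen by AIC; an
    ``incomplete_relaxation`` flag marks series that have not plateaued
    inside the observation window.
    """
    return SpectralRelaxationModel(times, nu, sigma=sigma).fit(max_components=max_components)


def overall_shift(nu0: float, nu_inf: float) -> float:
    """Overall dynamic Stokes shift delta_nu = nu(0) - nu(inf), cm^-1.

    A non-positive result (blue-shifting or null response) is returned
    but warned about.
    """
    if not (np.isfinite(nu0) and np.isfinite(nu_inf)):
        raise ValueError("nu0 and nu_inf must be finite")
    delta = float(nu0 - nu_inf)
    if delta <= 0:
        warnings.warn(
            f"delta_nu = {delta:.1f} cm^-1 <= 0: blue-shifting or null response", stacklevel=2
        )
    return delta


@dataclass(frozen=True)
class RelaxationTime:
    """tau_r by the analytic (sum a_i tau_i) and numeric-integral paths, ns."""

    analytic: float
    numeric: float

    @property
    def discrepancy(self) -> float:
        return abs(self.numeric - self.analytic) / self.analytic


def relaxation_time(result: SpectralRelaxationResult, warn_tol: float = 0.05) -> RelaxationTime:
    """Integral relaxation time of the normalised shift decay.

    Two routes are computed and both reported: (i) the analytic
    sum a_i tau_i of the fitted components (the primary value) and (ii) a
    trapezoidal integral of (nu(t) - nu_inf)/delta_nu over the observed
    series, completed with the fit's analytic head (0 -> t_first) and tail
    (t_last -> inf).  A discrepancy beyond ``warn_tol`` triggers a warning.
    """
    if result.delta_nu <= 0:
        raise ValueError("delta_nu <= 0: relaxation time undefined")
    analytic = result.tau_r
    t, nu = result.times, result.nu
    c = (nu - result.nu_inf) / result.delta_nu
    core = float(np.trapezoid(c, t))
    a_frac = result.amplitudes / result.amplitudes.sum()
    head = float(np.sum(a_frac * result.lifetimes * (1.0 - np.exp(-t[0] / result.lifetimes))))
    tail = float(np.sum(a_frac * result.lifetimes * np.exp(-t[-1] / result.lifetimes)))
    numeric = head + core + tail
    out = RelaxationTime(analytic=analytic, numeric=numeric)
    if out.discrepancy > warn_tol:
        warnings.warn(
            f"tau_r analytic ({analytic:.3g} ns) and numeric ({numeric:.3g} ns) paths "
            f"disagree by {100 * out.discrepancy:.1f}%",
            stacklevel=2,
        )
    return out


def estimate_time_zero(
    abs_polar: Spectrum, abs_ref: Spectrum, em_ref: Spectrum, jacobian: bool = True
) -> float:
    """Time-zero emission maximum nu(0) from steady-state spectra, cm^-1.

    Uses the standard reference-solvent construction: the absorption peak
    in the polar solvent, red-shifted by the Stokes shift measured in a
    nonpolar reference where no dipolar relaxation occurs,

        nu(0) = nu_abs,polar - (nu_abs,ref - nu_em,ref).

    Characteristic frequencies are peaks of asymmetric log-normal fits
    (consistent with the TRES maxima); a peak on the grid edge raises.
    """
    peaks = []
    for name, spec in (("abs_polar", abs_polar), ("abs_ref", abs_ref), ("em_ref", em_ref)):
        nu, inten = spec.to_wavenumber(jacobian=jacobian)
        shape = fit_lognormal(nu, inten)
        if shape.edge_peak:
            raise ValueError(f"{name} spectrum peaks at the grid edge; cannot characterise it")
        peaks.append(shape.nu_p)
    return float(peaks[0] - (peaks[1] - peaks[2]))


def bootstrap_uncertainty(
    fits,
    steady_state: Spectrum,
    time_grid=None,
    n_boot: int = 200,
    seed: int = 0,
    jacobian: bool = True,
    max_components: int = 3,
):
    """Parametric bootstrap of (delta_nu, tau_r) over the decay-fit covariances.

    Each resample draws amplitude/lifetime vectors from every decay fit's
    multivariate-normal parameter distribution, rebuilds the TRES,
    refits the maxima series, and recomputes the observables.  Fits
    without a covariance contribute their point estimates unchanged.
    Returns a dict with the resampled arrays and their standard deviations.
    """
    from copy import copy

    from .tres import default_time_grid, reconstruct_tres, tres_maxima

    if time_grid is None:
        time_grid = default_time_grid(fits, n_points=40)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    delta_nus, tau_rs = [], []
    for _ in range(n_boot):
        resampled = []
        for f in fits:
            g = copy(f)
            if f.covariance is not None:
                mean = np.concatenate([f.amplitudes, f.lifetimes])
                names = f.param_names
                idx = [
                    i
                    for i, n in enumerate(names)
                    if n.startswith("alpha") or n.startswith("tau")
                ]
                sub = f.covariance[np.ix_(idx, idx)]
                draw = rng.multivariate_normal(mean[: len(idx)], sub)
                k = f.amplitudes.size
                g.amplitudes = draw[:k]
                if draw.size > k:  # lifetimes free in this fit (per-curve route)
                    g.lifetimes = np.clip(draw[k:], 1e-4, None)
            resampled.append(g)
        try:
            tres = reconstruct_tres(resampled, steady_state, time_grid, jacobian=jacobian)
            res = tres_maxima(tres).fit(max_components=max_components)
            delta_nus.append(res.delta_nu)
            tau_rs.append(relaxation_time(res, warn_tol=np.inf).analytic)
        except (ValueError, RuntimeError):
            continue  # degenerate draw; skip
    delta_nus, tau_rs = np.array(delta_nus), np.array(tau_rs)
    return {
        "delta_nu_samples": delta_nus,
        "tau_r_samples": tau_rs,
        "delta_nu_std": float(delta_nus.std(ddof=1)) if delta_nus.size > 1 else float("nan"),
        "tau_r_std": float(tau_rs.std(ddof=1)) if tau_rs.size > 1 else float("nan"),
        "n_effective": int(delta_nus.size),
    }
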