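"""Multi-exponential TCSPC decay fitting by iterative reconvolution.

A measured fluorescence decay is the true impulse response blurred by the
instrument response function (IRF).  Rather than deconvolving the data,
the model

    m(t) = baseline + [IRF_shift (*) sum_j alpha_j exp(-t / tau_j)](t)

is convolved forward against the measured IRF (with a sub-channel shift
applied to the IRF by linear interpolation) and optimised against the
photon-counting histogram under Pearson chi^2 weighting, w = 1/max(c, 1).

`DecayModel(decay, irf).fit()` returns a :class:`DecayFitResult` carrying
amplitudes, lifetimes (sorted ascending), shift, baseline, the reduced
chi^2, and the covariance of the free parameters.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import nnls
from scipy.signal import fftconvolve

__all__ = [
    "DecayCurve",
    "DecayFitResult",
    "DecayModel",
    "convolve_model",
    "model_decay_noiseless",
    "fit_decay",
]


@dataclass(frozen=True)
class DecayCurve:
    """One TCSPC histogram: counts per channel at one emission wavelength.

    ``t0_channel`` marks the nominal excitation channel (IRF alignment
    reference); times are ``(k + 1/2 - t0_channel) * channel_width`` so a
    channel's time stamp is its midpoint.
    """

    counts: np.ndarray
    channel_width: float  # ns
    wavelength: float | None = None  # nm
    t0_channel: int = 0

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts)
        if counts.ndim != 1 or counts.size == 0:
            raise ValueError("counts must be a non-empty 1-d array")
        if np.any(counts < 0):
            raise ValueError("counts must be non-negative")
        if self.channel_width <= 0:
            raise ValueError(f"channel_width must be positive, got {self.channel_width}")
        object.__setattr__(self, "counts", counts.astype(float))

    @property
    def n_channels(self) -> int:
        return self.counts.size

    @property
    def times(self) -> np.ndarray:
        """Channel midpoint times in ns, relative to ``t0_channel``."""
        k = np.arange(self.n_channels, dtype=float)
        return (k + 0.5 - self.t0_channel) * self.channel_width

    @property
    def total_counts(self) -> float:
        return float(self.counts.sum())


def _shift_irf(irf_counts: np.ndarray, shift_channels: float) -> np.ndarray:
    """Shift the IRF by a (fractional) number of channels via linear interpolation."""
    n = irf_counts.size
    idx = np.arange(n, dtype=float) - shift_channels
    return np.interp(idx, np.arange(n, dtype=float), irf_counts, left=0.0, right=0.0)


def _multiexp(times: np.ndarray, amplitudes, lifetimes) -> np.ndarray:
    out = np.zeros_like(times)
    for a, tau in zip(amplitudes, lifetimes):
        out += a * np.exp(-np.clip(times, 0.0, None) / tau)
    out[times < 0] = 0.0
    return out


def convolve_model(
    irf: DecayCurve,
    amplitudes,
    lifetimes,
    shift: float = 0.0,
    baseline: float = 0.0,
) -> np.ndarray:
    """Model counts per channel: baseline + (shifted, unit-sum IRF) (*) multi-exp.

    The IRF is normalised to unit sum, so for a decay fully contained in
    the window the model integrates to ``sum_j alpha_j tau_j /
    channel_width + baseline * n_channels``.  ``shift`` is in ns and is
    applied to the IRF by linear interpolation (positive = IRF later).
    """
    lifetimes = np.asarray(lifetimes, dtype=float)
    if np.any(lifetimes <= 0):
        raise ValueError("lifetimes must be positive")
    area = irf.counts.sum()
    if area <= 0:
        raise ValueError("IRF has zero area")
    irf_n = _shift_irf(irf.counts / area, shift / irf.channel_width)
    t = (np.arange(irf.n_channels, dtype=float) + 0.5) * irf.channel_width
    decay = _multiexp(t, np.asarray(amplitudes, dtype=float), lifetimes)
    full = fftconvolve(irf_n, decay)[: irf.n_channels]
    return np.clip(full, 0.0, None) + baseline


def model_decay_noiseless(fit: "DecayFitResult", time_grid) -> np.ndarray:
    """IRF-free impulse response sum_j alpha_j exp(-t/tau_j) on ``time_grid`` (ns)."""
    t = np.asarray(time_grid, dtype=float)
    return _multiexp(t, fit.amplitudes, fit.lifetimes)


@dataclass
class DecayFitResult:
    """Reconvolution fit of one decay.

    Lifetimes are reported sorted ascending with amplitudes (and the
    covariance) permuted to match.
    """

    amplitudes: np.ndarray
    lifetimes: np.ndarray  # ns, ascending
    shift: float  # ns
    baseline: float  # counts
    chi2_reduced: float
    covariance: np.ndarray | None
    param_names: list[str]
    success: bool
    message: str
    n_points: int
    n_free: int
    decay: DecayCurve = field(repr=False)
    irf: DecayCurve = field(repr=False)
    window: slice = field(repr=False)

    @property
    def integral(self) -> float:
        """Analytic 0->inf integral of the impulse response, sum_j alpha_j tau_j (counts*ns)."""
        return float(np.sum(self.amplitudes * self.lifetimes))

    def model_counts(self) -> np.ndarray:
        """Best-fit convolved model on the measurement grid."""
        return convolve_model(self.irf, self.amplitudes, self.lifetimes, self.shift, self.baseline)

    def model_decay(self, time_grid) -> np.ndarray:
        return model_decay_noiseless(self, time_grid)

    def summary(self) -> str:
        lines = [
            "Reconvolution decay fit",
            "=======================",
            f"wavelength      : {self.decay.wavelength} nm",
            f"components      : {self.lifetimes.size}",
            f"chi2_reduced    : {self.chi2_reduced:.4f}",
            f"converged       : {self.success}",
            f"shift           : {self.shift:.4f} ns",
            f"baseline        : {self.baseline:.2f} counts",
            "  j      alpha_j       tau_j (ns)   frac(alpha*tau)",
        ]
        total = self.integral if self.integral != 0 else np.nan
        for j, (a, tau) in enumerate(zip(self.amplitudes, self.lifetimes)):
            lines.append(f"  {j}  {a:12.4g}  {tau:12.5g}   {a * tau / total:12.4g}")
        return "\n".join(lines)


class DecayModel:
    """Iterative-reconvolution model for one TCSPC decay.

    Parameters
    ----------
    decay, irf : DecayCurve
        Measured decay and instrument response on the same channel grid.
    n_components : int
        Number of exponentials (1-4); 3 is typical for Laurdan in bilayers.
    allow_negative : bool
        Permit negative amplitudes (rising decays at the red edge are
        physically expected in TDFS data).
    fit_baseline, fit_shift : bool
        Free the flat background / sub-channel IRF shift.
    """

    MAX_COMPONENTS = 4

    def __init__(
        self,
        decay: DecayCurve,
        irf: DecayCurve,
        n_components: int = 3,
        allow_negative: bool = True,
        fit_baseline: bool = True,
        fit_shift: bool = True,
    ) -> None:
        if not (1 <= n_components <= self.MAX_COMPONENTS):
            raise ValueError(f"n_components must be 1..{self.MAX_COMPONENTS}, got {n_components}")
        if irf.n_channels != decay.n_channels or not np.isclose(
            irf.channel_width, decay.channel_width
        ):
            raise ValueError("decay and IRF must share channel width and channel count")
        if decay.total_counts < 1000:
            raise ValueError(
                f"decay holds {decay.total_counts:.0f} counts; >= 1000 required for a stable fit"
            )
        self.decay = decay
        self.irf = irf
        self.n_components = n_components
        self.allow_negative = allow_negative
        self.fit_baseline = fit_baseline
        self.fit_shift = fit_shift
        self._dt = decay.channel_width
        self._window = self._fit_window()
        self._weights = 1.0 / np.sqrt(np.clip(decay.counts[self._window], 1.0, None))

    def _fit_window(self) -> slice:
        """Channels included in chi^2: from just before the IRF onset onward."""
        irf_c = self.irf.counts
        onset = int(np.argmax(irf_c > 1e-3 * irf_c.max()))
        return slice(max(onset - 2, 0), self.decay.n_channels)

    # -- initialisation -------------------------------------------------
    def _mean_decay_time(self) -> float:
        """Empirical first moment of the background-subtracted decay, ns."""
        c = self.decay.counts
        t = (np.arange(c.size, dtype=float) + 0.5) * self._dt
        t_irf = float(t[np.argmax(self.irf.counts)])
        bg = float(np.median(c[: max(self._window.start, 1)])) if self._window.start > 2 else 0.0
        tail = slice(int(np.argmax(self.irf.counts)), None)
        w = np.clip(c[tail] - bg, 0.0, None)
        denom = w.sum()
        tbar = float(((t[tail] - t_irf) * w).sum() / denom) if denom > 0 else 10 * self._dt
        return max(tbar, 2 * self._dt)

    # -- fitting --------------------------------------------------------
    # The nonlinear search runs over (log tau_j, shift) only; amplitudes
    # and baseline are projected out by weighted linear least squares at
    # every step (variable projection).  This removes the amplitude/
    # lifetime cancellation degeneracies that trap a full 2n+2-parameter
    # search in local minima.

    def _basis(self, taus: np.ndarray, shift: float) -> np.ndarray:
        cols = [convolve_model(self.irf, [1.0], [tau], shift=shift) for tau in taus]
        if self.fit_baseline:
            cols.append(np.ones(self.decay.n_channels))
        return np.column_stack(cols)[self._window]

    def _solve_linear(self, basis_w: np.ndarray, target_w: np.ndarray) -> np.ndarray:
        if self.allow_negative:
            coef, *_ = np.linalg.lstsq(basis_w, target_w, rcond=None)
            if self.fit_baseline and coef[-1] < 0:  # keep the background physical
                coef, *_ = np.linalg.lstsq(basis_w[:, :-1], target_w, rcond=None)
                coef = np.append(coef, 0.0)
        else:
            coef, _ = nnls(basis_w, target_w)
        return coef

    def _projected_residual(self, x: np.ndarray) -> np.ndarray:
        taus = np.exp(x[: self.n_components])
        shift = x[self.n_components] if self.fit_shift else 0.0
        basis_w = self._basis(taus, shift) * self._weights[:, None]
        target_w = self.decay.counts[self._window] * self._weights
        coef = self._solve_linear(basis_w, target_w)
        return target_w - basis_w @ coef

    def _full_residual(self, amps, taus, shift, baseline) -> np.ndarray:
        model = convolve_model(self.irf, amps, taus, shift, baseline)
        return (self.decay.counts[self._window] - model[self._window]) * self._weights

    #: deterministic multi-start ladder spans, as (low, high) multiples of
    #: the empirical mean decay time.  The wide 0.1x-10x ladder is a good
    #: start for plain decays; rising red-edge curves (negative
    #: amplitudes) are better served by compressed ladders.
    LADDER_SPANS = ((0.1, 10.0), (0.02, 1.0), (0.05, 2.5), (0.2, 4.0))

    def fit(self) -> DecayFitResult:
        from scipy.optimize import least_squares

        window_ns = self.decay.n_channels * self._dt
        tbar = float(np.clip(self._mean_decay_time(), self._dt, window_ns / 5.0))
        lo = np.full(self.n_components, np.log(self._dt / 10.0))
        hi = np.full(self.n_components, np.log(window_ns))
        if self.fit_shift:
            lo = np.append(lo, -10 * self._dt)
            hi = np.append(hi, 10 * self._dt)

        spans = self.LADDER_SPANS if self.n_components > 1 else ((1.0, 1.0),)
        # two-stage multistart: probe every ladder briefly, polish the best
        best = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for a, b in spans:
                if self.n_components == 1:
                    taus0 = np.array([tbar])
                else:
                    taus0 = np.geomspace(a * tbar, b * tbar, self.n_components)
                taus0 = np.clip(taus0, self._dt / 5.0, window_ns / 2.0)
                x0 = np.log(taus0)
                if self.fit_shift:
                    x0 = np.append(x0, 0.0)
                probe = least_squares(
                    self._projected_residual, x0, bounds=(lo, hi),
                    xtol=1e-8, ftol=1e-8, max_nfev=60 * x0.size,
                )
                if best is None or probe.cost < best.cost:
                    best = probe
            out = least_squares(
                self._projected_residual, best.x, bounds=(lo, hi),
                xtol=1e-10, ftol=1e-10, max_nfev=3000,
            )
        if not out.success:
            warnings.warn(f"decay fit did not converge: {out.message}", stacklevel=2)

        taus = np.exp(out.x[: self.n_components])
        shift = float(out.x[self.n_components]) if self.fit_shift else 0.0
        basis_w = self._basis(taus, shift) * self._weights[:, None]
        target_w = self.decay.counts[self._window] * self._weights
        coef = self._solve_linear(basis_w, target_w)
        amps = coef[: self.n_components]
        baseline = float(coef[-1]) if self.fit_baseline else 0.0

        order = np.argsort(taus)
        amps, taus = amps[order], taus[order]
        names = [f"alpha{j}" for j in range(self.n_components)] + [
            f"tau{j}" for j in range(self.n_components)
        ]
        if self.fit_shift:
            names.append("shift")
        if self.fit_baseline:
            names.append("baseline")

        n_pts = self._weights.size
        n_free = len(names)
        chi2 = float(np.sum(out.fun**2))
        chi2_red = chi2 / max(n_pts - n_free, 1)
        cov = self._covariance(amps, taus, shift, baseline, chi2_red)
        if cov is None:
            warnings.warn("singular covariance; parameter uncertainties omitted", stacklevel=2)
        return DecayFitResult(
            amplitudes=amps,
            lifetimes=taus,
            shift=shift,
            baseline=baseline,
            chi2_reduced=chi2_red,
            covariance=cov,
            param_names=names,
            success=bool(out.success),
            message=str(out.message),
            n_points=n_pts,
            n_free=n_free,
            decay=self.decay,
            irf=self.irf,
            window=self._window,
        )

    def _covariance(
        self, amps, taus, shift, baseline, chi2_red
    ) -> np.ndarray | None:
        """cov = chi2_red * (J^T J)^-1 with a forward-difference Jacobian
        of the weighted residual over the full free-parameter vector."""
        theta = list(amps) + list(taus)
        if self.fit_shift:
            theta.append(shift)
        if self.fit_baseline:
            theta.append(baseline)
        theta = np.asarray(theta, dtype=float)

        def unpack(v):
            k = self.n_components
            a, t = v[:k], v[k : 2 * k]
            s = v[2 * k] if self.fit_shift else 0.0
            b = v[2 * k + int(self.fit_shift)] if self.fit_baseline else 0.0
            return a, t, s, b

        r0 = self._full_residual(*unpack(theta))
        jac = np.empty((r0.size, theta.size))
        for i in range(theta.size):
            step = 1e-6 * max(abs(theta[i]), 1e-3)
            tp = theta.copy()
            tp[i] += step
            jac[:, i] = (self._full_residual(*unpack(tp)) - r0) / step
        jtj = jac.T @ jac
        try:
            return chi2_red * np.linalg.inv(jtj)
        except np.linalg.LinAlgError:
            return None


def fit_decay(
    decay: DecayCurve,
    irf: DecayCurve,
    n_components: int = 3,
    **kwargs,
) -> DecayFitResult:
    """Convenience wrapper: ``DecayModel(decay, irf, n_components, **kwargs).fit()``."""
    return DecayModel(decay, irf, n_components=n_components, **kwargs).fit()


@dataclass
class GlobalDecayResult:
    """Global (linked-lifetime) fit of a whole wavelength series.

    One shared lifetime ladder describes every decay; amplitudes (and
    baselines) are per wavelength.  ``fits`` exposes the result as a list
    of per-wavelength :class:`DecayFitResult` so downstream stages (TRES
    reconstruction) are agnostic to how the decays were fitted.
    """

    lifetimes: np.ndarray  # ns, ascending, shared
    amplitudes: np.ndarray  # (n_wavelengths, n_components)
    baselines: np.ndarray  # per wavelength
    shift: float
    chi2_reduced: float  # pooled over all wavelengths
    chi2_per_curve: np.ndarray
    cov_log_tau: np.ndarray | None  # covariance of (log tau_j [, shift])
    fits: list[DecayFitResult]
    success: bool
    message: str

    def summary(self) -> str:
        lines = [
            "Global reconvolution fit (shared lifetimes)",
            "===========================================",
            f"curves          : {self.amplitudes.shape[0]}",
            f"components      : {self.lifetimes.size}",
            f"lifetimes (ns)  : {np.array2string(self.lifetimes, precision=3)}",
            f"shift           : {self.shift:.4f} ns",
            f"pooled chi2_red : {self.chi2_reduced:.4f}",
            f"converged       : {self.success}",
            " wavelength  chi2_red",
        ]
        for f, c2 in zip(self.fits, self.chi2_per_curve):
            lines.append(f"  {f.decay.wavelength!s:>9}  {c2:8.4f}")
        return "\n".join(lines)


class GlobalDecayModel:
    """Linked-lifetime reconvolution fit of all wavelengths at once.

    In TDFS data the same emitting state is observed through every
    emission window, so a single set of lifetimes with wavelength-
    dependent (possibly negative) amplitudes is the natural model; it
    suppresses the per-wavelength fit artifacts that otherwise leak into
    the late-time reconstruction.  Amplitudes and baselines are projected
    out linearly (variable projection); the nonlinear search runs over
    the shared log-lifetimes and one shared IRF shift.
    """

    LADDER_SPANS = ((0.02, 1.0), (0.05, 2.5), (0.1, 10.0))

    def __init__(
        self,
        decays: list[DecayCurve],
        irf: DecayCurve,
        n_components: int = 5,
        allow_negative: bool = True,
        fit_baseline: bool = True,
        fit_shift: bool = True,
    ) -> None:
        if not decays:
            raise ValueError("no decays supplied")
        if not (1 <= n_components <= 8):
            raise ValueError(f"n_components must be 1..8, got {n_components}")
        n_ch, dt = irf.n_channels, irf.channel_width
        for d in decays:
            if d.n_channels != n_ch or not np.isclose(d.channel_width, dt):
                raise ValueError("all decays must share the IRF channel grid")
        self.decays = decays
        self.irf = irf
        self.n_components = n_components
        self.allow_negative = allow_negative
        self.fit_baseline = fit_baseline
        self.fit_shift = fit_shift
        self._dt = dt
        self._t = (np.arange(n_ch, dtype=float) + 0.5) * dt
        irf_c = irf.counts
        onset = int(np.argmax(irf_c > 1e-3 * irf_c.max()))
        self._window = slice(max(onset - 2, 0), n_ch)
        self._Y = np.array([d.counts[self._window] for d in decays])
        self._W = 1.0 / np.sqrt(np.clip(self._Y, 1.0, None))

    def _basis(self, taus: np.ndarray, shift: float) -> np.ndarray:
        cols = [convolve_model(self.irf, [1.0], [tau], shift=shift) for tau in taus]
        if self.fit_baseline:
            cols.append(np.ones(self.irf.n_channels))
        return np.column_stack(cols)[self._window]

    def _solve_curve(self, basis_w, target_w) -> np.ndarray:
        if self.allow_negative:
            coef, *_ = np.linalg.lstsq(basis_w, target_w, rcond=None)
            if self.fit_baseline and coef[-1] < 0:
                coef, *_ = np.linalg.lstsq(basis_w[:, :-1], target_w, rcond=None)
                coef = np.append(coef, 0.0)
        else:
            coef, _ = nnls(basis_w, target_w)
        return coef

    def _residual(self, x: np.ndarray) -> np.ndarray:
        taus = np.exp(x[: self.n_components])
        shift = x[self.n_components] if self.fit_shift else 0.0
        B = self._basis(taus, shift)
        out = []
        for i in range(self._Y.shape[0]):
            bw = B * self._W[i][:, None]
            tw = self._Y[i] * self._W[i]
            coef = self._solve_curve(bw, tw)
            out.append(tw - bw @ coef)
        return np.concatenate(out)

    def fit(self) -> GlobalDecayResult:
        from scipy.optimize import least_squares

        window_ns = self.irf.n_channels * self._dt
        # mean decay time of the aggregate photon stream
        total = self._Y.sum(axis=0)
        t_win = self._t[self._window]
        t_irf = self._t[np.argmax(self.irf.counts)]
        tbar = float(np.clip((np.clip(t_win - t_irf, 0, None) * total).sum() / total.sum(),
                             2 * self._dt, window_ns / 5.0))
        lo = np.full(self.n_components, np.log(self._dt / 10.0))
        hi = np.full(self.n_components, np.log(window_ns))
        if self.fit_shift:
            lo = np.append(lo, -10 * self._dt)
            hi = np.append(hi, 10 * self._dt)

        best = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for a, b in self.LADDER_SPANS:
                taus0 = np.clip(
                    np.geomspace(a * tbar, b * tbar, self.n_components),
                    self._dt / 5.0, window_ns / 2.0,
                )
                x0 = np.log(taus0)
                if self.fit_shift:
                    x0 = np.append(x0, 0.0)
                probe = least_squares(self._residual, x0, bounds=(lo, hi),
                                      xtol=1e-8, ftol=1e-8, max_nfev=40 * x0.size)
                if best is None or probe.cost < best.cost:
                    best = probe
            out = least_squares(self._residual, best.x, bounds=(lo, hi),
                                xtol=1e-10, ftol=1e-10, max_nfev=2000)
        if not out.success:
            warnings.warn(f"global decay fit did not converge: {out.message}", stacklevel=2)

        taus = np.exp(out.x[: self.n_components])
        shift = float(out.x[self.n_components]) if self.fit_shift else 0.0
        order = np.argsort(taus)
        taus = taus[order]
        B = self._basis(taus, shift)
        n_curves = self._Y.shape[0]
        amps = np.empty((n_curves, self.n_components))
        baselines = np.zeros(n_curves)
        chi2_per = np.empty(n_curves)
        fits = []
        n_free_curve = self.n_components + int(self.fit_baseline)
        for i, d in enumerate(self.decays):
            bw = B * self._W[i][:, None]
            tw = self._Y[i] * self._W[i]
            coef = self._solve_curve(bw, tw)
            amps[i] = coef[: self.n_components]
            if self.fit_baseline:
                baselines[i] = coef[-1]
            res = tw - bw @ coef
            chi2_per[i] = float(np.sum(res**2) / max(tw.size - n_free_curve, 1))
            # conditional covariance of this curve's linear coefficients
            try:
                cov_i = chi2_per[i] * np.linalg.inv(bw.T @ bw)
            except np.linalg.LinAlgError:
                cov_i = None
            names = [f"alpha{j}" for j in range(self.n_components)]
            if self.fit_baseline:
                names.append("baseline")
            fits.append(
                DecayFitResult(
                    amplitudes=amps[i].copy(),
                    lifetimes=taus.copy(),
                    shift=shift,
                    baseline=float(baselines[i]),
                    chi2_reduced=chi2_per[i],
                    covariance=cov_i,
                    param_names=names,
                    success=bool(out.success),
                    message=str(out.message),
                    n_points=tw.size,
                    n_free=n_free_curve,
                    decay=d,
                    irf=self.irf,
                    window=self._window,
                )
            )
        n_pts = self._Y.size
        n_free = self.n_components + int(self.fit_shift) + n_curves * n_free_curve
        chi2_red = float(np.sum(out.fun**2) / max(n_pts - n_free, 1))
        try:
            cov_x = chi2_red * np.linalg.inv(out.jac.T @ out.jac)
        except np.linalg.LinAlgError:
            cov_x = None
        return GlobalDecayResult(
            lifetimes=taus,
            amplitudes=amps,
            baselines=baselines,
            shift=shift,
            chi2_reduced=chi2_red,
            chi2_per_curve=chi2_per,
            cov_log_tau=cov_x,
            fits=fits,
            success=bool(out.success),
            message=str(out.message),
        )


def fit_decays_global(
    decays: list[DecayCurve], irf: DecayCurve, n_components: int = 5, **kwargs
) -> GlobalDecayResult:
    """Convenience wrapper over :class:`GlobalDecayModel`."""
    return GlobalDecayModel(decays, irf, n_components=n_components, **kwargs).fit()
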