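"""Asymmetric log-normal emission lineshape (Siano–Metzler form).

Broad emission bands of solvatochromic probes such as Laurdan are
conventionally fitted with a four-parameter asymmetric log-normal in
wavenumber space,

    g(nu) = h * exp(-ln2 * [ln(1 + alpha) / gamma]**2),
    alpha = 2 * gamma * (nu - nu_p) / delta,

which is zero wherever ``alpha <= -1`` and degenerates continuously to a
Gaussian of FWHM ``delta`` as ``gamma -> 0``.  ``nu_p`` is the peak
position (cm^-1), ``delta`` the width (cm^-1) and ``gamma`` the
dimensionless asymmetry (negative values skew the band to the red).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

__all__ = ["LogNormalShape", "lognormal_eval", "fit_lognormal"]

_LN2 = np.log(2.0)
# below this |gamma| the symmetric (Gaussian) branch is numerically safer
_GAMMA_SYM = 1e-7


@dataclass(frozen=True)
class LogNormalShape:
    """Parameters of one asymmetric log-normal band.

    Attributes
    ----------
    h : float
        Peak height (same units as the fitted intensities).
    nu_p : float
        Peak position in cm^-1.
    delta : float
        Width parameter in cm^-1 (equals the FWHM in the symmetric limit).
    gamma : float
        Asymmetry; 0 is a Gaussian.
    nu_p_err : float
        1-sigma uncertainty of ``nu_p`` from the fit covariance (nan when
        not estimated).
    edge_peak : bool
        True when the empirical maximum sat on the grid edge, so ``nu_p``
        is an extrapolation.
    """

    h: float
    nu_p: float
    delta: float
    gamma: float
    nu_p_err: float = float("nan")
    edge_peak: bool = False

    def __post_init__(self) -> None:
        if self.h <= 0:
            raise ValueError(f"peak height must be positive, got {self.h}")
        if self.delta <= 0:
            raise ValueError(f"width must be positive, got {self.delta}")

    def __call__(self, nu):
        return lognormal_eval(self, nu)

    @property
    def fwhm(self) -> float:
        """Full width at half maximum in cm^-1 (= delta*sinh(gamma)/gamma)."""
        g = self.gamma
        if abs(g) < _GAMMA_SYM:
            return self.delta
        return self.delta * np.sinh(g) / g


def lognormal_eval(shape: LogNormalShape, nu) -> np.ndarray:
    """Evaluate the band at wavenumbers ``nu`` (cm^-1).

    Returns 0 where the log argument ``1 + alpha`` is non-positive.
    """
    nu = np.asarray(nu, dtype=float)
    if abs(shape.gamma) < _GAMMA_SYM:
        x = 2.0 * (nu - shape.nu_p) / shape.delta
        return shape.h * np.exp(-_LN2 * x * x)
    alpha = 2.0 * shape.gamma * (nu - shape.nu_p) / shape.delta
    out = np.zeros_like(alpha)
    ok = alpha > -1.0
    x = np.log1p(alpha[ok]) / shape.gamma
    out[ok] = shape.h * np.exp(-_LN2 * x * x)
    return out


def _lognormal_func(nu, h, nu_p, delta, gamma):
    if abs(gamma) < _GAMMA_SYM:
        x = 2.0 * (nu - nu_p) / delta
        return h * np.exp(-_LN2 * x * x)
    alpha = 2.0 * gamma * (nu - nu_p) / delta
    out = np.zeros_like(alpha)
    ok = alpha > -1.0
    x = np.log1p(alpha[ok]) / gamma
    out[ok] = h * np.exp(-_LN2 * x * x)
    return out


def _initial_guess(nu: np.ndarray, y: np.ndarray) -> tuple[float, float, float, float]:
    """Deterministic start values from the empirical peak, FWHM and skew.

    Half-maximum crossings give left/right half widths l and r; for the
    Siano–Metzler form r/l = exp(gamma) and FWHM = delta*sinh(gamma)/gamma,
    which inverts to closed-form starting values.
    """
    i_max = int(np.argmax(y))
    h0 = float(y[i_max])
    nu_p0 = float(nu[i_max])
    half = h0 / 2.0

    def _cross(side: slice, reverse: bool) -> float | None:
        xs, ys = nu[side], y[side]
        if reverse:
            xs, ys = xs[::-1], ys[::-1]
        below = np.nonzero(ys < half)[0]
        if below.size == 0:
            return None
        j = below[0]
        if j == 0:
            return None
        # linear interpolation between the bracketing samples
        x1, x2, y1, y2 = xs[j - 1], xs[j], ys[j - 1], ys[j]
        return float(x1 + (half - y1) * (x2 - x1) / (y2 - y1))

    lo = _cross(slice(None, i_max + 1), reverse=True)
    hi = _cross(slice(i_max, None), reverse=False)
    span = float(nu[-1] - nu[0])
    left = (nu_p0 - lo) if lo is not None else span / 4.0
    right = (hi - nu_p0) if hi is not None else span / 4.0
    left = max(left, 1e-6 * span)
    right = max(right, 1e-6 * span)
    gamma0 = float(np.log(right / left))
    fwhm0 = left + right
    delta0 = fwhm0 if abs(gamma0) < _GAMMA_SYM else fwhm0 * gamma0 / np.sinh(gamma0)
    return h0, nu_p0, float(delta0), gamma0


def fit_lognormal(wavenumbers, intensities, sigma=None) -> LogNormalShape:
    """Least-squares fit of one spectral slice with the asymmetric log-normal.

    Parameters
    ----------
    wavenumbers, intensities : array-like
        One spectrum slice; at least 5 points, with at least one point on
        each side of the empirical maximum (otherwise the peak is flagged
        as extrapolated).
    sigma : array-like, optional
        Per-point 1-sigma noise used to weight the fit.

    Returns
    -------
    LogNormalShape
        Fitted parameters with ``nu_p_err`` from the covariance and an
        ``edge_peak`` flag when the maximum sat on the grid boundary.
    """
    nu = np.asarray(wavenumbers, dtype=float)
    y = np.asarray(intensities, dtype=float)
    if nu.ndim != 1 or nu.shape != y.shape:
        raise ValueError("wavenumbers and intensities must be matching 1-d arrays")
    if nu.size < 5:
        raise ValueError(f"need >= 5 points to fit 4 lineshape parameters, got {nu.size}")
    order = np.argsort(nu)
    nu, y = nu[order], y[order]
    if sigma is not None:
        sigma = np.asarray(sigma, dtype=float)[order]

    i_max = int(np.argmax(y))
    edge = i_max in (0, nu.size - 1)
    p0 = _initial_guess(nu, y)
    span = float(nu[-1] - nu[0])
    bounds = (
        [0.0, nu[0] - span, 1e-9 * span, -5.0],
        [np.inf, nu[-1] + span, 10.0 * span, 5.0],
    )
    p0 = (
        max(p0[0], 1e-300),
        float(np.clip(p0[1], bounds[0][1], bounds[1][1])),
        float(np.clip(p0[2], bounds[0][2], bounds[1][2])),
        float(np.clip(p0[3], -4.9, 4.9)),
    )
    popt, pcov = curve_fit(
        _lognormal_func, nu, y, p0=p0, sigma=sigma, bounds=bounds, maxfev=20000
    )
    nu_p_err = float(np.sqrt(pcov[1, 1])) if np.all(np.isfinite(pcov)) else float("nan")
    return LogNormalShape(
        h=float(popt[0]),
        nu_p=float(popt[1]),
        delta=float(popt[2]),
        gamma=float(popt[3]),
        nu_p_err=nu_p_err,
        edge_peak=edge,
    )
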