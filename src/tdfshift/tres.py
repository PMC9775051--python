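"""Time-resolved emission spectra (TRES) by spectral reconstruction.

Per-wavelength reconvolution fits give IRF-free impulse responses
d_lambda(t); normalising each to the steady-state intensity at its
wavelength,

    S(lambda, t) = I_ss(lambda) * d_lambda(t) / integral_0^inf d_lambda,

rebuilds the emission spectrum at every delay t — by construction the
time integral of the reconstruction reproduces the steady-state spectrum.
The surface is mapped to wavenumber (nu = 1e7 / lambda_nm, optionally
with the lambda^2 Jacobian on the intensities) and every time slice is
fitted with the asymmetric log-normal band, whose peak positions nu_p(t)
form the spectral-relaxation series nu(t).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .decay import DecayFitResult, model_decay_noiseless
from .lineshape import LogNormalShape, fit_lognormal, lognormal_eval

__all__ = [
    "Spectrum",
    "TRES",
    "reconstruct_tres",
    "tres_maxima",
    "default_time_grid",
    "LogNormalShape",
    "fit_lognormal",
    "lognormal_eval",
]

NM_CM = 1.0e7  # nm * cm^-1


@dataclass(frozen=True)
class Spectrum:
    """Steady-state spectrum: intensity vs wavelength (nm), strictly increasing."""

    wavelength: np.ndarray
    intensity: np.ndarray

    def __post_init__(self) -> None:
        wl = np.asarray(self.wavelength, dtype=float)
        inten = np.asarray(self.intensity, dtype=float)
        if wl.ndim != 1 or wl.shape != inten.shape or wl.size < 2:
            raise ValueError("wavelength and intensity must be matching 1-d arrays (>= 2 points)")
        if np.any(np.diff(wl) <= 0):
            raise ValueError("wavelengths must be strictly increasing")
        if np.any(inten < 0):
            raise ValueError("intensities must be non-negative")
        object.__setattr__(self, "wavelength", wl)
        object.__setattr__(self, "intensity", inten)

    def interp(self, wavelength_nm: float) -> float:
        """Linear interpolation; raises outside the measured support."""
        wl = self.wavelength
        if wavelength_nm < wl[0] or wavelength_nm > wl[-1]:
            raise ValueError(
                f"wavelength {wavelength_nm} nm outside steady-state support "
                f"[{wl[0]}, {wl[-1]}] nm"
            )
        return float(np.interp(wavelength_nm, wl, self.intensity))

    def to_wavenumber(self, jacobian: bool = True) -> tuple[np.ndarray, np.ndarray]:
        """(nu ascending in cm^-1, per-wavenumber intensity)."""
        nu = NM_CM / self.wavelength[::-1]
        inten = self.intensity[::-1]
        if jacobian:
            inten = inten * self.wavelength[::-1] ** 2 / NM_CM
        return nu, inten


@dataclass
class TRES:
    """Reconstructed intensity surface over (time, wavenumber) with per-time band fits."""

    times: np.ndarray  # ns, strictly increasing
    wavenumbers: np.ndarray  # cm^-1, ascending
    surface: np.ndarray  # shape (n_times, n_wavenumbers), >= 0
    fits: list[LogNormalShape] | None = None
    wavelengths: np.ndarray | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.wavenumbers = np.asarray(self.wavenumbers, dtype=float)
        self.surface = np.asarray(self.surface, dtype=float)
        if np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")
        if self.surface.shape != (self.times.size, self.wavenumbers.size):
            raise ValueError("surface must have shape (n_times, n_wavenumbers)")
        if np.any(self.surface < -1e-12 * max(self.surface.max(), 1.0)):
            raise ValueError("surface must be non-negative")

    def argmax_maxima(self) -> np.ndarray:
        """Grid-quantized nu(t) from the discrete argmax (cross-check output)."""
        return self.wavenumbers[np.argmax(self.surface, axis=1)]

    def plot(self, ax=None, n_slices: int = 6):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        idx = np.unique(np.linspace(0, self.times.size - 1, n_slices).astype(int))
        for i in idx:
            s = self.surface[i]
            ax.plot(self.wavenumbers, s / s.max(), label=f"t = {self.times[i]:.2g} ns")
        ax.set_xlabel(r"wavenumber (cm$^{-1}$)")
        ax.set_ylabel("normalized intensity")
        ax.legend(fontsize="small")
        return ax


def default_time_grid(
    fits: list[DecayFitResult], n_points: int = 100, span_factor: float = 5.0
) -> np.ndarray:
    """Log-spaced grid from 0.1 x channel width to span_factor x longest lifetime.

    Per fit, the longest lifetime carrying at least 1% of the integrated
    intensity is taken; the grid uses the median across wavelengths, so a
    runaway component in one noisy fit cannot stretch the grid into the
    signal-free tail.
    """
    dt = fits[0].decay.channel_width
    per_fit = []
    for f in fits:
        window = f.decay.n_channels * dt
        total = abs(np.sum(f.amplitudes * np.minimum(f.lifetimes, window)))
        sig = [
            min(tau, window)
            for a, tau in zip(f.amplitudes, f.lifetimes)
            if abs(a) * min(tau, window) > 0.01 * total
        ]
        per_fit.append(max(sig) if sig else 10 * dt)
    tau_max = max(float(np.median(per_fit)), 10 * dt)
    return np.geomspace(0.1 * dt, span_factor * tau_max, n_points)


def reconstruct_tres(
    fits: list[DecayFitResult],
    steady_state: Spectrum,
    time_grid=None,
    jacobian: bool = True,
    fit_slices: bool = True,
) -> TRES:
    """Reconstruct the TRES surface from per-wavelength fits and the steady state.

    Parameters
    ----------
    fits : list of DecayFitResult
        One reconvolution fit per emission wavelength (each fit's decay
        must carry its wavelength).
    steady_state : Spectrum
        Steady-state emission spectrum covering every fitted wavelength.
    time_grid : array-like, optional
        Delays (ns); defaults to :func:`default_time_grid`.
    jacobian : bool
        Apply the lambda^2/1e7 per-wavelength -> per-wavenumber intensity
        conversion (standard spectroscopic practice).
    fit_slices : bool
        Fit each time slice with the asymmetric log-normal (needs >= 5
        wavelengths).
    """
    if not fits:
        raise ValueError("no decay fits supplied")
    if time_grid is None:
        time_grid = default_time_grid(fits)
    t = np.asarray(time_grid, dtype=float)
    if np.any(t < 0):
        raise ValueError("time grid must be non-negative")

    wavelengths = []
    columns = []
    for f in fits:
        lam = f.decay.wavelength
        if lam is None:
            raise ValueError("every fitted decay must carry its emission wavelength")
        area = f.integral
        if area <= 0:
            raise ValueError(
                f"non-positive decay integral at {lam} nm; cannot normalize this wavelength"
            )
        d = model_decay_noiseless(f, t)
        col = steady_state.interp(lam) * d / area
        if jacobian:
            col = col * lam**2 / NM_CM
        wavelengths.append(lam)
        columns.append(col)

    wavelengths = np.asarray(wavelengths, dtype=float)
    nu = NM_CM / wavelengths
    order = np.argsort(nu)
    nu = nu[order]
    surface = np.column_stack([columns[i] for i in order])
    surface = np.clip(surface, 0.0, None)

    slice_fits = None
    if fit_slices and nu.size >= 5:
        slice_fits = [fit_lognormal(nu, surface[i]) for i in range(t.size)]
    return TRES(
        times=t,
        wavenumbers=nu,
        surface=surface,
        fits=slice_fits,
        wavelengths=wavelengths[order],
    )


def tres_maxima(tres: TRES):
    """Spectral-relaxation series nu(t) from the per-slice band-fit peaks.

    Peaks come from the fitted log-normal nu_p (not the grid-quantized
    argmax); per-point uncertainties and edge-peak flags are propagated.
    Returns a :class:`tdfshift.metrics.SolvationResponse`.
    """
    from .metrics import SolvationResponse

    if tres.fits is None:
        raise ValueError("TRES carries no per-slice lineshape fits")
    nu = np.array([f.nu_p for f in tres.fits])
    err = np.array([f.nu_p_err for f in tres.fits])
    flags = np.array([f.edge_peak for f in tres.fits])
    return SolvationResponse(
        times=tres.times.copy(),
        nu=nu,
        nu_err=err,
        flags=flags,
        nu_argmax=tres.argmax_maxima(),
    )
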