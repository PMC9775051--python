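"""Ground-truth-known synthetic data for every pipeline stage.

The generator emulates a TDFS experiment on a Laurdan-labelled bilayer:
an asymmetric log-normal emission band whose peak relaxes in time as

    nu(t) = nu_inf + delta_nu * sum_i a_i exp(-t / tau_i),

multiplied by a single-exponential population decay, convolved with a
Gaussian IRF and Poisson-sampled per emission wavelength (400-540 nm in
10 nm steps by default, matching a typical TCSPC acquisition).  It also
produces Laurdan GP intensity pairs and toy bilayer trajectories with
known particle densities, so the whole analysis is testable without any
measured data.

The default parameters are the study conditions used throughout the test
suite: delta_nu = 3000 cm^-1 and tau_r = sum a_i tau_i = 1.5 ns (a
fluid-phase, well-hydrated bilayer), population lifetime 4 ns
(Laurdan-like), band width 3000 cm^-1 with a mild red asymmetry, IRF FWHM
0.1 ns, and a 41 ns window at 20 ps channels.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.signal import fftconvolve

from .decay import DecayCurve
from .lineshape import LogNormalShape, lognormal_eval
from .mdprofiles import Trajectory
from .tres import NM_CM, TRES, Spectrum

__all__ = [
    "GroundTruth",
    "SyntheticDataset",
    "ToyGroup",
    "true_nu",
    "generate_tres_surface",
    "generate_dataset",
    "generate_gp_pair",
    "generate_toy_trajectory",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class GroundTruth:
    """True parameters of one synthetic TDFS experiment.

    ``components`` are (a_i, tau_i/ns) pairs of the spectral relaxation
    with sum a_i = 1; the overall shift is ``delta_nu`` and the unrelaxed
    peak is ``nu0 = nu_inf + delta_nu``.  The band keeps a fixed width and
    asymmetry over time unless ``width_slope`` (cm^-1/ns) is set.
    """

    nu_inf: float = 21000.0  # cm^-1, fully relaxed emission peak
    delta_nu: float = 3000.0  # cm^-1, overall dynamic Stokes shift
    components: tuple[tuple[float, float], ...] = ((0.5, 0.6), (0.5, 2.4))
    lifetime: float = 4.0  # ns, population decay
    linewidth: float = 3000.0  # cm^-1, log-normal width Delta
    asymmetry: float = -0.2  # log-normal gamma (red-skewed)
    irf_fwhm: float = 0.1  # ns
    irf_t0: float = 1.0  # ns, IRF center within the window
    channel_width: float = 0.02  # ns
    n_channels: int = 2048
    peak_counts: float = 1.0e4
    wavelengths: tuple[float, ...] = tuple(float(w) for w in range(400, 541, 10))
    seed: int = 0
    jacobian: bool = True
    width_slope: float = 0.0  # cm^-1/ns, robustness-test option

    def __post_init__(self) -> None:
        if self.delta_nu <= 0:
            raise ValueError("delta_nu must be positive")
        a = np.array([c[0] for c in self.components])
        tau = np.array([c[1] for c in self.components])
        if np.any(tau <= 0):
            raise ValueError("relaxation times must be positive")
        if abs(a.sum() - 1.0) > 1e-12:
            raise ValueError(f"relaxation amplitudes must sum to 1, got {a.sum()!r}")
        window = self.n_channels * self.channel_width
        needed = 5.0 * max(tau.max(), self.lifetime)
        if window < needed:
            raise ValueError(
                f"window {window:.1f} ns too short; needs >= 5 x max(tau, lifetime) = {needed:.1f} ns"
            )
        if self.peak_counts < 100:
            warnings.warn(
                f"peak_counts={self.peak_counts:g} < 100: decay fits will be unstable",
                stacklevel=2,
            )

    @property
    def nu0(self) -> float:
        """Unrelaxed (time-zero) emission peak, cm^-1."""
        return self.nu_inf + self.delta_nu

    @property
    def tau_r(self) -> float:
        """Integral relaxation time sum a_i tau_i, ns."""
        return float(sum(a * tau for a, tau in self.components))

    def lineshape_at(self, t: float) -> LogNormalShape:
        width = self.linewidth + self.width_slope * t
        return LogNormalShape(h=1.0, nu_p=true_nu(t, self), delta=width, gamma=self.asymmetry)


def true_nu(t, truth: GroundTruth) -> np.ndarray | float:
    """Ground-truth emission-peak position nu(t) in cm^-1 (t in ns, >= 0)."""
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("time must be non-negative")
    decay = np.zeros_like(t_arr)
    for a, tau in truth.components:
        decay = decay + a * np.exp(-t_arr / tau)
    out = truth.nu_inf + truth.delta_nu * decay
    return float(out) if np.isscalar(t) or t_arr.ndim == 0 else out


def _surface_on(truth: GroundTruth, times: np.ndarray, wavenumbers: np.ndarray) -> np.ndarray:
    """Noiseless S(t, nu) = exp(-t/lifetime) * lognormal(nu; nu(t))."""
    out = np.empty((times.size, wavenumbers.size))
    for i, t in enumerate(times):
        out[i] = np.exp(-t / truth.lifetime) * lognormal_eval(truth.lineshape_at(t), wavenumbers)
    return out


def generate_tres_surface(truth: GroundTruth, time_grid) -> TRES:
    """Noiseless ground-truth TRES on the wavenumber grid nu = 1e7 / wavelengths."""
    t = np.asarray(time_grid, dtype=float)
    if np.any(np.diff(t) <= 0) or np.any(t < 0):
        raise ValueError("time grid must be sorted, non-negative")
    nu = np.sort(NM_CM / np.asarray(truth.wavelengths, dtype=float))
    return TRES(times=t, wavenumbers=nu, surface=_surface_on(truth, t, nu), fits=None)


@dataclass
class SyntheticDataset:
    """One synthetic TCSPC acquisition plus its generating truth.

    ``decays`` are Poisson-sampled measured histograms (one per
    wavelength), ``noiseless_decays`` their expectations (IRF-convolved),
    and ``impulse_decays`` the IRF-free profiles whose channel-grid
    quadrature defines ``steady_state`` exactly.
    """

    decays: list[DecayCurve]
    irf: DecayCurve
    steady_state: Spectrum
    truth: GroundTruth
    noiseless_decays: list[np.ndarray] = field(repr=False, default_factory=list)
    impulse_decays: list[np.ndarray] = field(repr=False, default_factory=list)


def _gaussian_irf_counts(truth: GroundTruth) -> np.ndarray:
    t = (np.arange(truth.n_channels) + 0.5) * truth.channel_width
    sigma = truth.irf_fwhm * _FWHM_TO_SIGMA
    g = np.exp(-0.5 * ((t - truth.irf_t0) / sigma) ** 2)
    return truth.peak_counts * g


def generate_dataset(truth: GroundTruth, noisy_irf: bool = False) -> SyntheticDataset:
    """Generate a full per-wavelength TCSPC dataset with Poisson statistics.

    A root ``numpy.random.SeedSequence(truth.seed)`` is spawned into one
    child stream per wavelength (in wavelength order) plus one for the
    IRF, so regeneration with the same seed is bit-reproducible and
    per-wavelength streams are independent.
    """
    wavelengths = np.asarray(truth.wavelengths, dtype=float)
    t = (np.arange(truth.n_channels) + 0.5) * truth.channel_width
    dt = truth.channel_width

    # IRF-free impulse profiles per wavelength (intensity per channel)
    nu_lam = NM_CM / wavelengths
    impulse = _surface_on(truth, t, nu_lam).T  # (n_wavelengths, n_channels)
    if truth.jacobian:
        # per-wavelength intensity = per-wavenumber intensity * |dnu/dlambda|
        impulse = impulse * (NM_CM / wavelengths[:, None] ** 2)

    irf_counts = _gaussian_irf_counts(truth)
    irf_unit = irf_counts / irf_counts.sum()
    convolved = np.array(
        [fftconvolve(irf_unit, row)[: truth.n_channels] for row in impulse]
    )
    scale = truth.peak_counts / convolved.max()
    expectations = np.clip(convolved * scale, 0.0, None)
    impulse_scaled = impulse * scale

    root = np.random.SeedSequence(truth.seed)
    children = root.spawn(wavelengths.size + 1)
    decays = []
    for i, lam in enumerate(wavelengths):
        rng = np.random.default_rng(children[i])
        counts = rng.poisson(expectations[i]).astype(float)
        decays.append(DecayCurve(counts=counts, channel_width=dt, wavelength=float(lam)))
    if noisy_irf:
        rng = np.random.default_rng(children[-1])
        irf_obs = rng.poisson(irf_counts).astype(float)
    else:
        irf_obs = irf_counts
    irf = DecayCurve(counts=irf_obs, channel_width=dt, wavelength=None)

    # steady state = exact channel-grid quadrature of the impulse profiles,
    # so noiseless decays integrate to it identically (the normalization
    # identity the TRES reconstruction inverts)
    steady = Spectrum(wavelength=wavelengths, intensity=impulse_scaled.sum(axis=1) * dt)
    return SyntheticDataset(
        decays=decays,
        irf=irf,
        steady_state=steady,
        truth=truth,
        noiseless_decays=[row for row in expectations],
        impulse_decays=[row for row in impulse_scaled],
    )


def generate_gp_pair(
    gp_true: float, total: float, seed: int | None = None, noiseless: bool = False
) -> tuple[float, float]:
    """Poisson-noised (I440, I490) pair with GP expectation ``gp_true``.

    Expectations are total*(1+gp)/2 and total*(1-gp)/2.
    """
    if not -1.0 <= gp_true <= 1.0:
        raise ValueError(f"gp_true must lie in [-1, 1], got {gp_true}")
    if total <= 0:
        raise ValueError("total intensity must be positive")
    mu440 = total * (1.0 + gp_true) / 2.0
    mu490 = total * (1.0 - gp_true) / 2.0
    if noiseless:
        return mu440, mu490
    rng = np.random.default_rng(seed)
    return float(rng.poisson(mu440)), float(rng.poisson(mu490))


@dataclass(frozen=True)
class ToyGroup:
    """z-distribution recipe for one toy atom group.

    kind "gaussian_mirrored": Gaussians at +/-center (Angstrom from the
    membrane midplane), half the atoms per leaflet; "gaussian": single
    Gaussian at ``center``; "uniform": uniform across the box.
    """

    count: int
    kind: str = "gaussian_mirrored"
    center: float = 20.0
    sigma: float = 3.0

    def __post_init__(self) -> None:
        if self.count <= 0:
            raise ValueError("group count must be positive")
        if self.kind not in ("gaussian_mirrored", "gaussian", "uniform"):
            raise ValueError(f"unknown toy group kind {self.kind!r}")
        if self.sigma <= 0 and self.kind != "uniform":
            raise ValueError("sigma must be positive")


def generate_toy_trajectory(
    n_frames: int,
    groups: dict[str, ToyGroup],
    box: tuple[float, float, float] = (64.0, 64.0, 100.0),
    seed: int = 0,
    lipids_per_leaflet: int | None = None,
) -> Trajectory:
    """Toy bilayer trajectory with i.i.d. per-frame coordinates.

    z is drawn from each group's stated distribution about the membrane
    midplane (placed at Lz/2 in box coordinates, i.e. profiles are
    centered at z=0 after membrane centering); x, y are uniform in the
    box.  The box is constant across frames.
    """
    if n_frames <= 0:
        raise ValueError("empty trajectory: n_frames must be positive")
    if not groups:
        raise ValueError("at least one atom group is required")
    lx, ly, lz = (float(v) for v in box)
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    names, specs = zip(*groups.items())
    counts = [g.count for g in specs]
    n_atoms = int(np.sum(counts))
    starts = np.concatenate([[0], np.cumsum(counts)])
    atom_groups = {
        name: np.arange(starts[i], starts[i + 1]) for i, name in enumerate(names)
    }

    positions = np.empty((n_frames, n_atoms, 3))
    positions[:, :, 0] = rng.uniform(0.0, lx, size=(n_frames, n_atoms))
    positions[:, :, 1] = rng.uniform(0.0, ly, size=(n_frames, n_atoms))
    for i, g in enumerate(specs):
        sl = slice(starts[i], starts[i + 1])
        n = g.count
        if g.kind == "uniform":
            z = rng.uniform(-lz / 2.0, lz / 2.0, size=(n_frames, n))
        elif g.kind == "gaussian":
            z = rng.normal(g.center, g.sigma, size=(n_frames, n))
        else:  # mirrored leaflets: first half upper, second half lower
            half = n // 2
            sign = np.where(np.arange(n) < half, 1.0, -1.0)
            z = rng.normal(g.center * sign, g.sigma, size=(n_frames, n))
        positions[:, sl, 2] = (z + lz / 2.0) % lz
    boxes = np.tile([lx, ly, lz], (n_frames, 1))
    return Trajectory(
        positions=positions,
        boxes=boxes,
        atom_groups=atom_groups,
        lipids_per_leaflet=lipids_per_leaflet,
    )
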