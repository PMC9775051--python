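"""Laurdan generalized polarization (GP).

GP = (I440 - I490) / (I440 + I490) is the classic steady-state ratio of
Laurdan emission at 440 nm (gel-like, dehydrated environment) and 490 nm
(fluid, hydrated environment).  It mixes hydration and mobility effects
and here serves as the steady-state companion to the time-resolved
observables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .tres import Spectrum

__all__ = ["GPRecord", "compute_gp", "gp_from_spectrum", "gp_table"]


def compute_gp(i440: float, i490: float) -> float:
    """GP = (I440 - I490) / (I440 + I490); both intensities zero is an error."""
    if i440 < 0 or i490 < 0:
        raise ValueError("intensities must be non-negative")
    total = i440 + i490
    if total <= 0:
        raise ValueError("I440 + I490 must be positive")
    return float((i440 - i490) / total)


def _band_integral(spectrum: Spectrum, center: float, half_width: float) -> float:
    lo, hi = center - half_width, center + half_width
    wl = spectrum.wavelength
    if lo < wl[0] or hi > wl[-1]:
        raise ValueError(
            f"band [{lo}, {hi}] nm outside spectrum support [{wl[0]}, {wl[-1]}] nm"
        )
    inside = wl[(wl > lo) & (wl < hi)]
    grid = np.concatenate([[lo], inside, [hi]])
    vals = np.interp(grid, wl, spectrum.intensity)
    return float(np.trapezoid(vals, grid))


def gp_from_spectrum(
    spectrum: Spectrum, band_440: float = 440.0, band_490: float = 490.0, half_width: float = 5.0
) -> float:
    """GP from trapezoidal band integrals over ±half_width nm windows.

    ``half_width=0`` falls back to point intensities at the band centers.
    """
    if half_width == 0:
        return compute_gp(spectrum.interp(band_440), spectrum.interp(band_490))
    i440 = _band_integral(spectrum, band_440, half_width)
    i490 = _band_integral(spectrum, band_490, half_width)
    return compute_gp(i440, i490)


@dataclass(frozen=True)
class GPRecord:
    """One GP measurement under labelled conditions (pH, Ca2+ mM, composition, ...)."""

    i440: float
    i490: float
    condition: tuple[tuple[str, object], ...] = field(default_factory=tuple)

    def __post_init__(self) -> None:
        compute_gp(self.i440, self.i490)  # validates
        if isinstance(self.condition, dict):
            object.__setattr__(self, "condition", tuple(sorted(self.condition.items())))

    @property
    def gp(self) -> float:
        return compute_gp(self.i440, self.i490)


def gp_table(
    records: list[GPRecord], n_boot: int = 1000, ci: float = 95.0, seed: int = 0
) -> pd.DataFrame:
    """Mean GP with percentile bootstrap CIs per condition cell.

    Records sharing the same condition labels are pooled; the CI is the
    percentile interval of bootstrap resamples of the per-record GPs
    (collapsing to the point estimate for a single record).  Deterministic
    for a given seed.
    """
    if not records:
        raise ValueError("no GP records supplied")
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    lo_q, hi_q = (100.0 - ci) / 2.0, 100.0 - (100.0 - ci) / 2.0

    cells: dict[tuple, list[float]] = {}
    for rec in records:
        cells.setdefault(rec.condition, []).append(rec.gp)

    rows = []
    for cond, gps in cells.items():
        gps = np.asarray(gps)
        if gps.size == 1:
            lo = hi = float(gps[0])
        else:
            boots = rng.choice(gps, size=(n_boot, gps.size), replace=True).mean(axis=1)
            lo, hi = (float(v) for v in np.percentile(boots, [lo_q, hi_q]))
        row = dict(cond)
        row.update(
            gp_mean=float(gps.mean()),
            gp_ci_low=lo,
            gp_ci_high=hi,
            n=int(gps.size),
        )
        rows.append(row)
    df = pd.DataFrame(rows)
    keys = [c for c in df.columns if c not in ("gp_mean", "gp_ci_low", "gp_ci_high", "n")]
    return df.set_index(keys) if keys else df
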