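"""Bilayer trajectory post-processing: density profiles and area per lipid.

Profiles are number densities along the membrane normal (z), referenced to
the membrane center (phosphate center of geometry by default, computed as
a circular mean over the periodic z axis) and optionally symmetrized,
rho(z) <- (rho(z) + rho(-z)) / 2.  Area per lipid is the lateral box area
divided by the lipids per leaflet, block-averaged over frames.

File I/O (GRO topology + XTC/TRR coordinates) goes through MDAnalysis;
the in-memory :class:`Trajectory` is a plain array container so the
operations stay testable without touching disk.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Trajectory",
    "DensityProfile",
    "APLSeries",
    "center_membrane",
    "density_profile",
    "peak_stats",
    "area_per_lipid",
    "load_trajectory",
    "write_trajectory",
]

A3_PER_NM3 = 1000.0  # Angstrom^3 per nm^3


@dataclass
class Trajectory:
    """Coordinates (Angstrom) for F frames of N atoms plus named atom groups.

    ``positions`` has shape (F, N, 3); ``boxes`` (F, 3) holds the
    orthorhombic box edges (Lx, Ly, Lz).  ``atom_groups`` maps group names
    (e.g. "PO4", "CA", "H3O") to atom-index arrays.
    """

    positions: np.ndarray
    boxes: np.ndarray
    atom_groups: dict[str, np.ndarray] = field(default_factory=dict)
    lipids_per_leaflet: int | None = None

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_atoms, 3)")
        if self.n_frames == 0:
            raise ValueError("empty trajectory (0 frames)")
        if self.boxes.shape != (self.n_frames, 3):
            raise ValueError("boxes must have shape (n_frames, 3)")
        if np.any(self.boxes <= 0):
            raise ValueError("box dimensions must be positive")
        n_atoms = self.positions.shape[1]
        groups = {}
        for name, idx in self.atom_groups.items():
            idx = np.asarray(idx, dtype=int)
            if idx.size and (idx.min() < 0 or idx.max() >= n_atoms):
                raise ValueError(f"group {name!r} has indices outside 0..{n_atoms - 1}")
            groups[name] = idx
        self.atom_groups = groups

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_atoms(self) -> int:
        return self.positions.shape[1]


@dataclass
class DensityProfile:
    """Per-group number density (nm^-3) vs distance from the membrane center (Angstrom)."""

    z_centers: np.ndarray
    densities: dict[str, np.ndarray]
    bin_width: float
    n_frames: int
    symmetrized: bool
    box_area: float  # mean lateral area, Angstrom^2

    def plot(self, ax=None, groups=None):
        """Quick-look profile plot; returns the matplotlib axes."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        for name in groups or self.densities:
            ax.plot(self.z_centers, self.densities[name], label=name)
        ax.set_xlabel("z (Å)")
        ax.set_ylabel("number density (nm$^{-3}$)")
        ax.legend()
        return ax


@dataclass
class APLSeries:
    """Per-frame area per lipid with a block-averaged mean and standard error."""

    values: np.ndarray  # Angstrom^2 per frame
    mean: float
    std_error: float
    n_blocks: int

    def summary(self) -> str:
        return (
            f"Area per lipid: {self.mean:.3f} ± {self.std_error:.3f} Å² "
            f"({self.mean / 100:.4f} nm², {self.values.size} frames, {self.n_blocks} blocks)"
        )


def _circular_mean_z(z: np.ndarray, lz: float) -> float:
    """Center of a periodic coordinate set via the circular (angular) mean."""
    theta = 2.0 * np.pi * z / lz
    s, c = np.sin(theta).mean(), np.cos(theta).mean()
    if np.hypot(s, c) < 0.05:
        # e.g. leaflets exactly half a box apart: any center fits equally
        warnings.warn(
            "reference group is (nearly) antipodally symmetric over the periodic "
            "z axis; its circular-mean center is ill-defined",
            stacklevel=3,
        )
    mean_angle = np.arctan2(s, c)
    return float((lz * mean_angle / (2.0 * np.pi)) % lz)


def _wrap_centered(z: np.ndarray, lz: float) -> np.ndarray:
    """Wrap z into [-lz/2, lz/2)."""
    return (z + lz / 2.0) % lz - lz / 2.0


def center_membrane(
    positions: np.ndarray, box: np.ndarray, reference_indices: np.ndarray
) -> np.ndarray:
    """Recenter one frame so the reference group's center of geometry is at z=0.

    The center is a circular mean over the periodic z axis, so a reference
    group wrapped across the boundary is handled correctly; x and y are
    left untouched and z is wrapped into [-Lz/2, Lz/2).
    """
    reference_indices = np.asarray(reference_indices, dtype=int)
    if reference_indices.size == 0:
        raise ValueError("reference group is empty")
    lz = float(box[2])
    out = np.array(positions, dtype=float, copy=True)
    zc = _circular_mean_z(out[reference_indices, 2], lz)
    out[:, 2] = _wrap_centered(out[:, 2] - zc, lz)
    return out


def density_profile(
    traj: Trajectory,
    groups: list[str] | None = None,
    bin_width: float = 1.0,
    symmetrize: bool = True,
    center: bool = True,
    reference_group: str = "PO4",
) -> DensityProfile:
    """Frame-averaged number-density profiles along z.

    Each frame is recentered on ``reference_group`` (circular mean over
    the periodic z axis), coordinates are wrapped into the slab
    [-Lz/2, Lz/2) taken from the first frame, and per-group histograms are
    normalised by the bin volume Lx*Ly*bin_width.  The z box edge must be
    constant across frames (within 1%); with ``symmetrize`` the profile is
    mirror-averaged about z=0.
    """
    if groups is None:
        groups = list(traj.atom_groups)
    missing = [g for g in groups if g not in traj.atom_groups]
    if missing:
        raise KeyError(f"unknown atom groups: {missing}")
    lz = float(traj.boxes[0, 2])
    if np.any(np.abs(traj.boxes[:, 2] - lz) > 0.01 * lz):
        raise ValueError("z box edge varies by more than 1% across frames; use a fixed slab")
    n_bins = int(round(lz / bin_width))
    if n_bins < 2 or abs(n_bins * bin_width - lz) > 1e-6 * lz:
        raise ValueError(
            f"bin_width {bin_width} Å does not evenly divide the z box edge {lz} Å"
        )
    if symmetrize and n_bins % 2:
        raise ValueError("symmetrization needs an even number of bins (mirror pairs)")
    edges = np.linspace(-lz / 2.0, lz / 2.0, n_bins + 1)
    centers = 0.5 * (edges[:-1] + edges[1:])

    ref_idx = traj.atom_groups.get(reference_group) if center else None
    if center and (ref_idx is None or ref_idx.size == 0):
        raise ValueError(f"centering requested but reference group {reference_group!r} is empty")

    sums = {g: np.zeros(n_bins) for g in groups}
    for f in range(traj.n_frames):
        box = traj.boxes[f]
        frame = traj.positions[f]
        if center:
            frame = center_membrane(frame, box, ref_idx)
        z = _wrap_centered(frame[:, 2], lz)
        # inclusive right edge so an atom exactly at +Lz/2 lands in the last bin
        bin_vol_nm3 = box[0] * box[1] * bin_width / A3_PER_NM3
        for g in groups:
            idx = traj.atom_groups[g]
            counts, _ = np.histogram(z[idx], bins=edges)
            sums[g] += counts / bin_vol_nm3
    densities = {g: s / traj.n_frames for g, s in sums.items()}
    if symmetrize:
        densities = {g: 0.5 * (d + d[::-1]) for g, d in densities.items()}
    return DensityProfile(
        z_centers=centers,
        densities=densities,
        bin_width=bin_width,
        n_frames=traj.n_frames,
        symmetrized=symmetrize,
        box_area=float(np.mean(traj.boxes[:, 0] * traj.boxes[:, 1])),
    )


@dataclass
class PeakStats:
    position: float  # Angstrom
    height: float  # nm^-3
    flat: bool


def peak_stats(profile: DensityProfile, group: str) -> PeakStats:
    """Position and height of a group's density maximum.

    The maximum bin is refined by a parabola through its two neighbours;
    a flat profile is flagged rather than raising.
    """
    d = profile.densities[group]
    z = profile.z_centers
    if np.allclose(d, d[0]):
        return PeakStats(position=float("nan"), height=float(d[0]), flat=True)
    i = int(np.argmax(d))
    if 0 < i < d.size - 1:
        y0, y1, y2 = d[i - 1], d[i], d[i + 1]
        denom = y0 - 2.0 * y1 + y2
        frac = 0.5 * (y0 - y2) / denom if denom != 0 else 0.0
        frac = float(np.clip(frac, -0.5, 0.5))
        pos = z[i] + frac * profile.bin_width
        height = y1 - 0.25 * (y0 - y2) * frac
    else:
        pos, height = z[i], d[i]
    return PeakStats(position=float(pos), height=float(height), flat=False)


def rank_groups_by_peak(profile: DensityProfile, groups: list[str]) -> list[str]:
    """Groups ordered by |peak position| (innermost first) — ion-binding comparison."""
    return sorted(groups, key=lambda g: abs(peak_stats(profile, g).position))


def area_per_lipid(traj: Trajectory, n_blocks: int = 5) -> APLSeries:
    """Per-frame APL = Lx*Ly / lipids_per_leaflet (Angstrom^2), block-averaged."""
    if not traj.lipids_per_leaflet or traj.lipids_per_leaflet <= 0:
        raise ValueError("lipids_per_leaflet must be a positive integer")
    apl = traj.boxes[:, 0] * traj.boxes[:, 1] / traj.lipids_per_leaflet
    n_blocks = max(1, min(n_blocks, apl.size))
    blocks = np.array_split(apl, n_blocks)
    means = np.array([b.mean() for b in blocks])
    se = float(means.std(ddof=1) / np.sqrt(n_blocks)) if n_blocks > 1 else 0.0
    return APLSeries(values=apl, mean=float(apl.mean()), std_error=se, n_blocks=n_blocks)


# ---------------------------------------------------------------------------
# MDAnalysis-backed I/O
# ---------------------------------------------------------------------------

def load_trajectory(
    topology: str,
    trajectory: str | None = None,
    selections: dict[str, str] | None = None,
    lipids_per_leaflet: int | None = None,
) -> Trajectory:
    """Read a GRO/PDB (+ XTC/TRR) trajectory into an in-memory :class:`Trajectory`.

    ``selections`` maps group names to MDAnalysis selection strings, e.g.
    ``{"PO4": "name P*", "CA": "resname CA"}``.
    """
    import MDAnalysis as mda

    u = mda.Universe(topology, trajectory) if trajectory else mda.Universe(topology)
    groups = {
        name: u.select_atoms(sel).ix.copy() for name, sel in (selections or {}).items()
    }
    positions, boxes = [], []
    for ts in u.trajectory:
        positions.append(ts.positions.copy())
        boxes.append(ts.dimensions[:3].copy())
    return Trajectory(
        positions=np.array(positions),
        boxes=np.array(boxes),
        atom_groups=groups,
        lipids_per_leaflet=lipids_per_leaflet,
    )


def write_trajectory(traj: Trajectory, gro_path: str, xtc_path: str | None = None) -> None:
    """Write a Trajectory as a single-frame GRO plus an optional XTC."""
    import MDAnalysis as mda

    n = traj.n_atoms
    names = np.full(n, "X", dtype=object)
    resnames = np.full(n, "TOY", dtype=object)
    for gname, idx in traj.atom_groups.items():
        names[idx] = gname[:5]
        resnames[idx] = gname[:4].upper() or "TOY"
    # one residue per atom keeps group names recoverable from resnames
    u2 = mda.Universe.empty(n, n_residues=n, atom_resindex=np.arange(n), trajectory=True)
    u2.add_TopologyAttr("names", list(names))
    u2.add_TopologyAttr("resnames", list(resnames))
    u2.add_TopologyAttr("resids", list(range(1, n + 1)))
    u2.load_new(traj.positions, order="fac")
    box = np.column_stack([traj.boxes, np.full((traj.n_frames, 3), 90.0)])
    for f, ts in enumerate(u2.trajectory):
        ts.dimensions = box[f]
    with mda.Writer(gro_path, n_atoms=n) as w:
        u2.trajectory[0]
        w.write(u2.atoms)
    if xtc_path is not None:
        with mda.Writer(xtc_path, n_atoms=n) as w:
            for ts in u2.trajectory:
                w.write(u2.atoms)
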