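"""Bilayer post-processing: centering, density profiles, peaks, APL."""

import numpy as np
import pytest

from tdfshift import (
    ToyGroup,
    Trajectory,
    area_per_lipid,
    center_membrane,
    density_profile,
    generate_toy_trajectory,
    peak_stats,
)
from tdfshift.mdprofiles import load_trajectory, rank_groups_by_peak, write_trajectory

BOX = (64.0, 64.0, 100.0)


@pytest.fixture(scope="module")
def toy():
    return generate_toy_trajectory(
        n_frames=60,
        groups={
            "PO4": ToyGroup(count=400, center=20.0, sigma=2.0),
            "CA": ToyGroup(count=120, center=23.0, sigma=2.5),
            "W": ToyGroup(count=1500, kind="uniform"),
        },
        box=BOX,
        seed=11,
        lipids_per_leaflet=64,
    )


class TestCenterMembrane:
    def test_already_centered_is_identity(self):
        pos = np.array([[1.0, 2.0, 38.0], [3.0, 4.0, 42.0]])
        ref = np.array([0, 1])
        out = center_membrane(pos, np.array(BOX), ref)
        # reference centroid at z=40 -> recentered symmetric about 0
        assert out[:, 2] == pytest.approx([-2.0, 2.0])
        out2 = center_membrane(out + [0, 0, 0], np.array(BOX), ref)
        assert np.allclose(out2, out)

    def test_uniform_shift_is_removed(self):
        rng = np.random.default_rng(0)
        pos = rng.uniform(0, 60, size=(50, 3))
        ref = np.arange(50)
        a = center_membrane(pos, np.array(BOX), ref)
        b = center_membrane(pos + [0.0, 0.0, 5.0], np.array(BOX), ref)
        assert np.allclose(a[:, 2], b[:, 2], atol=1e-9)

    def test_group_wrapped_across_boundary(self):
        """A reference group split by the periodic image centers correctly."""
        lz = BOX[2]
        z_unwrapped = np.array([78.0, 79.0, 81.0, 82.0])  # centroid at 80 = 0 mod lz
        pos_wrapped = np.zeros((4, 3))
        pos_wrapped[:, 2] = z_unwrapped % lz
        out = center_membrane(pos_wrapped, np.array(BOX), np.arange(4))
        assert np.sort(out[:, 2]) == pytest.approx([-2.0, -1.0, 1.0, 2.0])

    def test_empty_reference_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            center_membrane(np.zeros((4, 3)), np.array(BOX), np.array([], dtype=int))


class TestDensityProfile:
    def test_mirrored_gaussians_peak_at_generating_center(self, toy):
        profile = density_profile(toy, bin_width=1.0)
        peak = peak_stats(profile, "PO4")
        assert abs(abs(peak.position) - 20.0) <= 0.5  # within half a bin

    def test_symmetrized_profile_is_mirror_symmetric(self, toy):
        profile = density_profile(toy, bin_width=1.0, symmetrize=True)
        for dens in profile.densities.values():
            assert np.array_equal(dens, dens[::-1])

    def test_symmetrization_is_idempotent(self, toy):
        p = density_profile(toy, bin_width=1.0, symmetrize=True)
        for dens in p.densities.values():
            assert np.allclose(dens, 0.5 * (dens + dens[::-1]), rtol=0, atol=0)

    def test_histogram_conservation(self, toy):
        """Integral of density x area x dz recovers the group atom count."""
        profile = density_profile(toy, bin_width=1.0, symmetrize=False)
        bin_vol_nm3 = BOX[0] * BOX[1] * profile.bin_width / 1000.0
        for name, idx in toy.atom_groups.items():
            total = profile.densities[name].sum() * bin_vol_nm3
            assert total == pytest.approx(idx.size, rel=1e-9)

    def test_invariant_under_rigid_z_translation(self, toy):
        shifted = Trajectory(
            positions=np.concatenate(
                [toy.positions[..., :2], (toy.positions[..., 2:] + 7.3) % BOX[2]], axis=2
            ),
            boxes=toy.boxes,
            atom_groups=toy.atom_groups,
            lipids_per_leaflet=toy.lipids_per_leaflet,
        )
        a = density_profile(toy, bin_width=1.0)
        b = density_profile(shifted, bin_width=1.0)
        for name in a.densities:
            assert np.allclose(a.densities[name], b.densities[name], atol=1e-9)

    def test_uneven_bin_width_rejected(self, toy):
        with pytest.raises(ValueError, match="evenly divide"):
            density_profile(toy, bin_width=0.7)

    def test_water_density_matches_uniform_expectation(self, toy):
        """1500 atoms in 64x64x100 A^3 -> 3.66 atoms/nm^3 at mid-plane bins."""
        profile = density_profile(toy, bin_width=1.0, symmetrize=True)
        expected = 1500 / (BOX[0] * BOX[1] * BOX[2] / 1000.0)
        middle = np.abs(profile.z_centers) < 10
        assert profile.densities["W"][middle].mean() == pytest.approx(expected, rel=0.05)


class TestPeakStats:
    def test_uniform_profile_is_flagged(self, toy):
        profile = density_profile(toy, bin_width=1.0)
        profile.densities["flat"] = np.ones_like(profile.z_centers)
        assert peak_stats(profile, "flat").flat

    def test_doubling_density_doubles_height_not_position(self, toy):
        profile = density_profile(toy, bin_width=1.0)
        ref = peak_stats(profile, "CA")
        profile.densities["CA2"] = 2.0 * profile.densities["CA"]
        doubled = peak_stats(profile, "CA2")
        assert doubled.height == pytest.approx(2 * ref.height, rel=1e-12)
        assert doubled.position == ref.position

    def test_group_ordering_by_peak_distance(self, toy):
        profile = density_profile(toy, bin_width=1.0)
        assert rank_groups_by_peak(profile, ["CA", "PO4"]) == ["PO4", "CA"]


class TestAreaPerLipid:
    def test_constant_box_exact_value(self, toy):
        apl = area_per_lipid(toy)
        assert np.all(apl.values == 64.0)  # 64*64/64 A^2
        assert apl.mean == 64.0
        assert apl.std_error == 0.0

    def test_two_frame_mean(self):
        traj = Trajectory(
            positions=np.zeros((2, 4, 3)) + 1.0,
            boxes=np.array([[60.0, 64.0, 80.0], [70.0, 64.0, 80.0]]),
            atom_groups={"PO4": np.arange(4)},
            lipids_per_leaflet=64,
        )
        apl = area_per_lipid(traj, n_blocks=2)
        assert apl.values == pytest.approx([60.0, 70.0])
        assert apl.mean == pytest.approx(65.0)

    def test_missing_leaflet_count_rejected(self, toy):
        bare = Trajectory(
            positions=toy.positions, boxes=toy.boxes, atom_groups=toy.atom_groups
        )
        with pytest.raises(ValueError, match="lipids_per_leaflet"):
            area_per_lipid(bare)

    def test_summary_reports_nm2(self, toy):
        assert "0.6400 nm²" in area_per_lipid(toy).summary()


class TestTrajectoryValidation:
    def test_zero_frames_rejected(self):
        with pytest.raises(ValueError, match="empty trajectory"):
            Trajectory(positions=np.zeros((0, 4, 3)), boxes=np.zeros((0, 3)))

    def test_out_of_range_group_indices_rejected(self):
        with pytest.raises(ValueError, match="indices"):
            Trajectory(
                positions=np.zeros((1, 4, 3)),
                boxes=np.ones((1, 3)),
                atom_groups={"PO4": np.array([9])},
            )


def test_gro_xtc_roundtrip(tmp_path, toy):
    """Write GRO+XTC via MDAnalysis and read back within XTC precision."""
    gro, xtc = str(tmp_path / "toy.gro"), str(tmp_path / "toy.xtc")
    write_trajectory(toy, gro, xtc)
    back = load_trajectory(
        gro, xtc, selections={"PO4": "name PO4"}, lipids_per_leaflet=64
    )
    assert back.n_frames == toy.n_frames
    assert back.atom_groups["PO4"].size == 400
    assert np.abs(back.positions - toy.positions).max() < 0.01  # XTC stores 0.001 nm
    prof_a = density_profile(toy, bin_width=1.0)
    prof_b = density_profile(back, bin_width=1.0)
    assert np.allclose(
        prof_a.densities["PO4"], prof_b.densities["PO4"], atol=0.05 * prof_a.densities["PO4"].max()
    )
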