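"""Tomogram emulation: voxelisation, degradation, extraction, corrections."""

import numpy as np
import pytest

from pgk.assembly import SphereAssembly, VoxelVolume
from pgk.contacts import contact_graph, n_touch_distribution, packing_fraction
from pgk.lattices import LatticeSpec, build_lattice, perturb_assembly
from pgk.tomo import (DegradationSpec, degrade, extract_spheres,
                      regularize_spheres, rescale_assembly, voxelize)


def single_sphere(R=105.0, L=400.0):
    return SphereAssembly([[L / 2] * 3], [R], [L] * 3, [False] * 3)


def three_sphere_fixture():
    return SphereAssembly([[150.0, 150, 150], [450.0, 200, 180],
                           [300.0, 450, 420]],
                          [80.0, 70.0, 90.0], [600.0] * 3, [False] * 3)


def dense_disordered_fixture(jammed, phi=0.55, d_target=210.0):
    """A walled, non-touching dense disordered assembly.

    Derived from a jammed packing by shrinking radii in place (separating
    all contacts by ~10 nm, inside the 15 nm touching tolerance) and
    padding the box so nothing wraps or touches a face.
    """
    a = jammed.copy()
    a.radii = a.radii * (phi / (a.sphere_volume() / a.volume)) ** (1 / 3)
    scale = d_target / (2 * float(a.radii.mean()))
    a.positions = a.wrapped().positions * scale
    a.radii = a.radii * scale
    a.box = a.box * scale
    pad = float(a.radii.max()) + 20.0
    a.positions = a.positions + pad
    a.box = a.box + 2 * pad
    a.periodic = np.array([False] * 3)
    a.labels = None
    return a


class TestVoxelize:
    def test_single_sphere_volume_convergence(self):
        a = single_sphere()
        vol = voxelize(a, pitch=5.0)
        v_vox = np.count_nonzero(vol.grid) * 5.0 ** 3
        v_true = 4 / 3 * np.pi * 105.0 ** 3
        assert abs(v_vox - v_true) / v_true < 0.02

    def test_refinement_improves_phi(self):
        a = three_sphere_fixture()
        phi_true = float(packing_fraction(a))
        errs = []
        for pitch in (20.0, 10.0):
            vol = voxelize(a, pitch=pitch)
            errs.append(abs(vol.occupancy_fraction() - phi_true))
        assert errs[1] < errs[0]

    def test_labels_are_particle_indices(self):
        a = three_sphere_fixture()
        vol = voxelize(a, pitch=10.0)
        assert set(np.unique(vol.grid)) == {0, 1, 2, 3}

    def test_periodic_wrap(self):
        a = SphereAssembly([[0.0, 0.0, 200.0]], [50.0], [400.0] * 3,
                           [True, True, False])
        vol = voxelize(a, pitch=10.0)
        # the sphere straddles the x=0 and y=0 faces: corners all occupied
        assert vol.grid[0, 0, 20] == 1
        assert vol.grid[-1, -1, 20] == 1

    def test_memory_budget(self):
        a = single_sphere(L=10000.0)
        with pytest.raises(MemoryError, match="pitch"):
            voxelize(a, pitch=1.0, max_voxels=10_000_000)


class TestDegrade:
    def test_identity_spec(self):
        vol = voxelize(three_sphere_fixture(), pitch=10.0)
        out = degrade(vol, DegradationSpec())
        np.testing.assert_array_equal(out.grid > 0, vol.grid > 0)

    def test_shrink_volume_scaling(self):
        vol = voxelize(single_sphere(), pitch=4.0)
        out = degrade(vol, DegradationSpec(shrink_factor=0.8, seed=1))
        ratio = np.count_nonzero(out.grid) / np.count_nonzero(vol.grid)
        assert abs(ratio - 0.8 ** 3) < 0.05 * 0.8 ** 3 + 0.02

    def test_deterministic_given_seed(self):
        vol = voxelize(three_sphere_fixture(), pitch=10.0)
        spec = DegradationSpec(shrink_factor=0.85, deform_amplitude=10.0,
                               noise_rate=0.01, seed=42)
        np.testing.assert_array_equal(degrade(vol, spec).grid,
                                      degrade(vol, spec).grid)

    def test_invalid_specs_rejected(self):
        with pytest.raises(ValueError):
            DegradationSpec(shrink_factor=0.0)
        with pytest.raises(ValueError):
            DegradationSpec(noise_rate=0.5)


class TestExtractSpheres:
    def test_three_sphere_round_trip(self):
        a = three_sphere_fixture()
        vol = voxelize(a, pitch=10.0)
        rec = extract_spheres(vol)
        assert rec.n == 3
        # match recovered to true by nearest centre
        for p, r in zip(a.positions, a.radii):
            d = np.linalg.norm(rec.positions - p, axis=1)
            k = np.argmin(d)
            assert d[k] <= 10.0          # within one voxel pitch
            assert abs(rec.radii[k] - r) / r < 0.05

    def test_empty_volume_returns_none(self):
        vol = VoxelVolume(np.zeros((10, 10, 10), dtype=int), 10.0)
        assert extract_spheres(vol) is None

    def test_all_occupied_gives_single_particle(self):
        vol = VoxelVolume(np.ones((12, 12, 12), dtype=int), 10.0)
        rec = extract_spheres(vol)
        assert rec.n == 1

    def test_dense_disordered_assembly_recovery(self, small_jammed_packing):
        """Voxelize -> extract recovers N and phi at phi ~ 0.5."""
        a = dense_disordered_fixture(small_jammed_packing)
        vol = voxelize(a, pitch=15.0)
        rec = extract_spheres(vol, expected_radius=float(a.radii.mean()))
        assert abs(rec.n - a.n) / a.n <= 0.05
        phi_true = a.sphere_volume() / a.volume
        phi_rec = rec.sphere_volume() / rec.volume
        assert abs(phi_rec - phi_true) <= 0.03


class TestCorrections:
    def test_rescale_linearity(self):
        a = three_sphere_fixture()
        out = rescale_assembly(a, 1.2)
        np.testing.assert_allclose(out.positions, 1.2 * a.positions)
        np.testing.assert_allclose(out.radii, 1.2 * a.radii)
        assert float(packing_fraction(out)) == pytest.approx(
            float(packing_fraction(a)), rel=1e-9)

    def test_rescale_preserves_contacts_with_scaled_gap(self):
        a = build_lattice(LatticeSpec(kind="diamond", repeats=(2, 2, 2)))
        s1 = n_touch_distribution(contact_graph(a, gap_tol=10.0))
        b = rescale_assembly(a, 1.2)
        s2 = n_touch_distribution(contact_graph(b, gap_tol=12.0))
        assert s1.histogram == s2.histogram

    def test_rescale_identity(self):
        a = three_sphere_fixture()
        out = rescale_assembly(a, 1.0)
        np.testing.assert_array_equal(out.positions, a.positions)

    def test_regularize_sets_uniform_diameter(self):
        a = three_sphere_fixture()
        out = regularize_spheres(a, 252.0)
        assert np.all(out.radii == 126.0)
        np.testing.assert_array_equal(out.positions, a.positions)
        assert out.meta["regularized_diameter_nm"] == 252.0

    def test_regularize_reports_no_overlaps_when_shrinking(self):
        a = three_sphere_fixture()
        out = regularize_spheres(a, 100.0)  # smaller than all diameters
        assert out.meta["overlap_pairs"] == 0


class TestEndToEndChain:
    shrink = 0.83
    gap = 15.0

    def run_chain(self, a):
        vol = voxelize(a, pitch=15.0)
        degraded = degrade(vol, DegradationSpec(shrink_factor=self.shrink,
                                                deform_amplitude=5.0,
                                                noise_rate=0.002, seed=5))
        rec = extract_spheres(
            degraded, expected_radius=self.shrink * float(a.radii.mean()))
        return rescale_assembly(rec, 1.0 / self.shrink)

    def test_chain_preserves_mean_contact_number(self, small_jammed_packing):
        """generate -> voxelize -> degrade(0.83) -> extract -> rescale(1.2)
        recovers the pre-degradation mean n_touch within 0.5."""
        a = dense_disordered_fixture(small_jammed_packing)
        true_mean = n_touch_distribution(
            contact_graph(a, self.gap)).n_touch_mean
        corrected = self.run_chain(a)
        assert abs(corrected.n - a.n) / a.n < 0.05
        rec_mean = n_touch_distribution(
            contact_graph(corrected, self.gap)).n_touch_mean
        assert abs(rec_mean - true_mean) <= 0.5

    def test_chain_preserves_diamond_classification(self):
        """Tetrahedral input survives the degradation/correction chain."""
        a = build_lattice(LatticeSpec(kind="diamond", lattice_parameter=490.0,
                                      repeats=(3, 3, 3)))
        a = perturb_assembly(a, 4.0, seed=11)
        a.periodic[:] = False
        corrected = self.run_chain(a)
        assert abs(corrected.n - a.n) / a.n < 0.05

        from pgk.boo import averaged_boo, classify_structure, reference_points
        res = averaged_boo(corrected, gap_tol=self.gap)
        label, _ = classify_structure(res.ensemble_mean(4),
                                      res.ensemble_mean(6),
                                      reference_points(include_mrj=False))
        assert label == "diamond"
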