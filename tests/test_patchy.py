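"""Patchy-particle model: potentials, alignment, gradients, integration."""

import math

import numpy as np
import pytest
from scipy.optimize import minimize_scalar
from scipy.spatial.transform import Rotation

from pgk.assembly import SphereAssembly
from pgk.patchy import (PatchyModel, SimSettings, equilibrate_to_density,
                        make_settling_start, patch_alignment_factor,
                        radial_potential, run_langevin, total_energy)
from pgk.patchy import _forces, _pair_candidates, _integrate, _kinetic


def quat_align(v, target):
    """Unit quaternion (w, x, y, z) rotating v onto target."""
    v = np.asarray(v, float) / np.linalg.norm(v)
    t = np.asarray(target, float) / np.linalg.norm(target)
    rot, _ = Rotation.align_vectors([t], [v])
    return np.roll(rot.as_quat(), 1)


IDENT = np.array([1.0, 0, 0, 0])


class TestRadialPotential:
    def test_minimum_at_two_to_the_one_over_n(self):
        m = PatchyModel()
        res = minimize_scalar(lambda r: radial_potential(r, "patch_lj", m),
                              bounds=(150.0, 300.0), method="bounded")
        assert res.x / m.sigma == pytest.approx(2 ** (1 / 24), rel=1e-6)

    def test_zero_at_sigma_and_depth_at_minimum(self):
        m = PatchyModel()
        assert radial_potential(m.sigma, "patch_lj", m) == pytest.approx(0.0)
        r_min = m.sigma * 2 ** (1 / 24)
        assert radial_potential(r_min, "patch_lj", m) == pytest.approx(
            -m.eps_patch, rel=1e-12)
        # the body term lives at the sphere-radius length scale
        r_min_b = m.body_sigma_factor * m.sigma * 2 ** (1 / 24)
        assert radial_potential(r_min_b, "body_lj", m) == pytest.approx(
            -m.eps_body, rel=1e-12)
        # and is negligible at contact distance
        assert abs(radial_potential(m.sigma, "body_lj", m)) < 1e-5

    def test_wca_cutoff_continuity(self):
        m = PatchyModel()
        r_c = m.sigma * 2 ** (1 / 24)
        assert radial_potential(r_c, "wca", m) == pytest.approx(0.0, abs=1e-10)
        assert radial_potential(r_c + 1e-9, "wca", m) == 0.0
        # derivative ~ 0 at the cutoff from inside
        h = 1e-4
        du = (radial_potential(r_c - h, "wca", m)
              - radial_potential(r_c - 2 * h, "wca", m)) / h
        assert abs(du) < 1e-2

    def test_domain_errors(self):
        m = PatchyModel()
        with pytest.raises(ValueError):
            radial_potential(0.0, "patch_lj", m)
        with pytest.raises(ValueError):
            radial_potential(100.0, "bogus", m)


class TestPatchGeometry:
    def test_tetrahedral_angles_validated(self):
        bad = np.array([[1, 0, 0], [0, 1, 0], [0, 0, 1],
                        [-1, 0, 0.0]])
        with pytest.raises(ValueError, match="tetrahedral"):
            PatchyModel(patch_axes=bad)

    def test_default_axes_pairwise_cosine(self):
        m = PatchyModel()
        dots = m.patch_axes @ m.patch_axes.T
        off = dots[~np.eye(4, dtype=bool)]
        np.testing.assert_allclose(off, -1 / 3, atol=1e-12)

    def test_odd_exponent_rejected(self):
        with pytest.raises(ValueError):
            PatchyModel(n_exp=23)


class TestPatchAlignmentFactor:
    def test_facing_patches_give_unity(self):
        m = PatchyModel()
        u = np.array([1.0, 1.0, 1.0]) / math.sqrt(3)
        qj = quat_align([1, 1, 1], -u)
        f = patch_alignment_factor(IDENT, qj, u * m.sigma, m)
        assert f == pytest.approx(1.0, abs=1e-12)

    def test_worst_alignment_is_effectively_zero(self):
        """A patch at >= 90 deg misalignment contributes < 1e-6.

        The modulation switches off entirely at 3x the halfwidth (90 deg
        for the 30 deg default), so an orthogonal patch pair has factor 0.
        """
        from pgk.patchy import _alignment_g

        m = PatchyModel()  # halfwidth 30 deg
        g90 = _alignment_g(math.pi / 2, m.delta_rad)
        assert g90 * g90 < 1e-6
        assert g90 == 0.0
        # smooth decay towards the cutoff
        angles = np.linspace(0, math.pi / 2, 200)
        vals = [_alignment_g(t, m.delta_rad) for t in angles]
        assert all(b <= a + 1e-12 for a, b in zip(vals, vals[1:]))

    def test_symmetric_under_exchange(self, rng):
        m = PatchyModel()
        for _ in range(5):
            qi = np.roll(Rotation.random(
                random_state=np.random.RandomState(rng.integers(2**31))).as_quat(), 1)
            qj = np.roll(Rotation.random(
                random_state=np.random.RandomState(rng.integers(2**31))).as_quat(), 1)
            r = rng.normal(size=3) * 100
            f_ij = patch_alignment_factor(qi, qj, r, m)
            f_ji = patch_alignment_factor(qj, qi, -r, m)
            assert f_ij == pytest.approx(f_ji, rel=1e-12)

    def test_bounded_unit_interval(self, rng):
        m = PatchyModel()
        for _ in range(20):
            qi = np.roll(Rotation.random(
                random_state=np.random.RandomState(rng.integers(2**31))).as_quat(), 1)
            qj = np.roll(Rotation.random(
                random_state=np.random.RandomState(rng.integers(2**31))).as_quat(), 1)
            f = patch_alignment_factor(qi, qj, rng.normal(size=3) * 100, m)
            assert 0.0 <= f <= 1.0


def lab_frame_state(n, lx=8.0, seed=0, zlo=1.0, zhi=4.0, min_sep=0.97):
    """Random non-overlapping reduced-unit state above the wall."""
    rng = np.random.default_rng(seed)
    pos = []
    while len(pos) < n:
        cand = np.array([rng.uniform(0, lx), rng.uniform(0, lx),
                         rng.uniform(zlo, zhi)])
        ok = True
        for p in pos:
            d = cand - p
            d[0] -= lx * round(d[0] / lx)
            d[1] -= lx * round(d[1] / lx)
            if np.linalg.norm(d) < min_sep:
                ok = False
                break
        if ok:
            pos.append(cand)
    quat = np.roll(Rotation.random(n, random_state=np.random.RandomState(
        seed + 1)).as_quat(), 1, axis=1)
    return np.ascontiguousarray(pos), np.ascontiguousarray(quat)


class TestForcesAreGradients:
    def test_translational_forces_match_central_difference(self):
        m = PatchyModel(gravity=0.7)
        lx = 8.0
        pos, quat = lab_frame_state(20, lx=lx, seed=3)

        def energy(p):
            pairs = _pair_candidates(p, lx, lx, m.r_cut)
            e, _, _ = _forces(np.ascontiguousarray(p), quat, pairs, lx, lx, m)
            return e

        pairs = _pair_candidates(pos, lx, lx, m.r_cut)
        _, F, _ = _forces(pos, quat, pairs, lx, lx, m)
        h = 1e-6
        scale = max(1.0, np.abs(F).max())
        for i in range(0, 20, 3):
            for a in range(3):
                pp = pos.copy(); pp[i, a] += h
                pm = pos.copy(); pm[i, a] -= h
                num = -(energy(pp) - energy(pm)) / (2 * h)
                assert abs(num - F[i, a]) / scale < 1e-6

    def test_torques_match_central_difference(self):
        m = PatchyModel()
        lx = 8.0
        pos, quat = lab_frame_state(12, lx=lx, seed=5, min_sep=1.0)

        def energy(q):
            pairs = _pair_candidates(pos, lx, lx, m.r_cut)
            e, _, _ = _forces(pos, np.ascontiguousarray(q), pairs, lx, lx, m)
            return e

        pairs = _pair_candidates(pos, lx, lx, m.r_cut)
        _, _, T = _forces(pos, quat, pairs, lx, lx, m)
        h = 1e-6
        scale = max(1.0, np.abs(T).max())
        for i in range(0, 12, 2):
            for a in range(3):
                ax = np.zeros(3); ax[a] = 1.0

                def rotated(sign):
                    w1, x1, y1, z1 = np.roll(
                        Rotation.from_rotvec(ax * sign * h).as_quat(), 1)
                    w2, x2, y2, z2 = quat[i]
                    out = quat.copy()
                    out[i] = [w1*w2 - x1*x2 - y1*y2 - z1*z2,
                              w1*x2 + x1*w2 + y1*z2 - z1*y2,
                              w1*y2 - x1*z2 + y1*w2 + z1*x2,
                              w1*z2 + x1*y2 - y1*x2 + z1*w2]
                    return out
                num = -(energy(rotated(+1)) - energy(rotated(-1))) / (2 * h)
                assert abs(num - T[i, a]) / scale < 1e-6


class TestTotalEnergy:
    def make_assembly(self, pos_red, quat, m, lx=8.0, lz=10.0):
        return SphereAssembly(np.asarray(pos_red) * m.sigma,
                              np.full(len(pos_red), m.sigma / 2),
                              np.array([lx, lx, lz]) * m.sigma,
                              [True, True, False], orientations=quat)

    def test_bound_dimer_energy_default_model(self):
        """Facing patches at the LJ minimum bind with -eps_patch; the body
        term at the radius scale contributes nothing at contact."""
        m = PatchyModel(gravity=0.0)
        r_min = 2 ** (1 / 24)
        u = np.array([0.0, 0.0, 1.0])
        quat = np.array([quat_align([1, 1, 1], u),
                         quat_align([1, 1, 1], -u)])
        a = self.make_assembly([[4, 4, 3], [4, 4, 3 + r_min]], quat, m)
        e = total_energy(a, m)
        assert e == pytest.approx(-m.eps_patch, abs=5e-3)

    def test_bound_dimer_energy_sticky_body_variant(self):
        """With the body LJ at the contact length both minima coincide and
        the bond deepens to -(eps_patch + eps_body) = -11 k_BT."""
        m = PatchyModel(gravity=0.0, body_sigma_factor=1.0)
        r_min = 2 ** (1 / 24)
        u = np.array([0.0, 0.0, 1.0])
        quat = np.array([quat_align([1, 1, 1], u),
                         quat_align([1, 1, 1], -u)])
        a = self.make_assembly([[4, 4, 3], [4, 4, 3 + r_min]], quat, m)
        e = total_energy(a, m)
        assert e == pytest.approx(-(m.eps_patch + m.eps_body), abs=8e-3)

    def test_single_particle_gravity(self):
        m = PatchyModel(gravity=1.3)
        a = self.make_assembly([[4.0, 4.0, 5.0]], np.array([IDENT]), m)
        assert total_energy(a, m) == pytest.approx(1.3 * 5.0, abs=1e-9)

    def test_distant_particles_zero_energy(self):
        m = PatchyModel(gravity=0.0)
        quat = np.tile(IDENT, (3, 1))
        a = self.make_assembly([[1, 1, 3], [5, 5, 3], [3, 3, 7]], quat, m)
        assert total_energy(a, m) == pytest.approx(0.0, abs=1e-12)

    def test_translation_invariance_lateral(self):
        m = PatchyModel(gravity=0.0)
        pos, quat = lab_frame_state(10, seed=8)
        a = self.make_assembly(pos, quat, m)
        e0 = total_energy(a, m)
        b = a.copy()
        b.positions = b.positions + np.array([137.0, -55.0, 0.0])
        assert total_energy(b.wrapped(), m) == pytest.approx(e0, rel=1e-9)


class TestLangevin:
    def test_nve_energy_conservation_dimer(self):
        """Zero friction, zero gravity: < 1% drift over 1e4 steps."""
        m = PatchyModel(gravity=0.0)
        r_min = 2 ** (1 / 24)
        pos = np.array([[4.0, 4.0, 3.0], [4.0, 4.0, 3.0 + r_min]])
        quat = np.array([quat_align([1, 1, 1], [0, 0, 1]),
                         quat_align([1, 1, 1], [0, 0, -1])])
        rng = np.random.default_rng(2)
        vel = rng.normal(0, 0.4, (2, 3))
        ang = rng.normal(0, 1.0, (2, 3))
        s = SimSettings(dt=0.002, steps=10_000, seed=2)
        pairs = _pair_candidates(pos, 8.0, 8.0, m.r_cut)
        e0, _, _ = _forces(pos, quat, pairs, 8.0, 8.0, m)
        tot0 = e0 + _kinetic(vel, ang)
        ef = _integrate(pos, quat, vel, ang, m, s, 10_000, 8.0, 8.0,
                        np.random.default_rng(0), friction=0.0)
        tot1 = ef + _kinetic(vel, ang)
        assert abs(tot1 - tot0) / abs(tot0) < 0.01

    def test_deterministic_given_seed(self):
        m = PatchyModel(gravity=0.5)
        start = make_settling_start(40, m, lateral=8.0, seed=4)
        s = SimSettings(steps=500, seed=9, validate_dt=False)
        a = run_langevin(start, m, s)[-1]
        b = run_langevin(start, m, s)[-1]
        np.testing.assert_array_equal(a.positions, b.positions)
        np.testing.assert_array_equal(a.orientations, b.orientations)

    def test_particles_never_below_wall(self):
        m = PatchyModel(gravity=2.0)
        start = make_settling_start(40, m, lateral=8.0, seed=4)
        s = SimSettings(steps=3000, seed=1, snapshot_stride=500,
                        validate_dt=False)
        for snap in run_langevin(start, m, s):
            assert snap.positions[:, 2].min() > 0.0

    def test_unreachable_density_target_raises(self):
        """Targets above the disordered-sediment ceiling exhaust the
        gravity bracket and raise with the achieved values."""
        m = PatchyModel(gravity=0.5)
        s = SimSettings(steps=4000, seed=3, validate_dt=False)
        with pytest.raises(RuntimeError, match="unreachable"):
            equilibrate_to_density(m, 0.73, s, n=250, lateral=6.0,
                                   max_iters=2)

    def test_bad_dt_fails_nve_precondition(self):
        m = PatchyModel(gravity=0.5)
        start = make_settling_start(30, m, lateral=8.0, seed=4)
        with pytest.raises(ValueError, match="NVE"):
            run_langevin(start, m, SimSettings(dt=0.05, steps=100, seed=1))

    def test_plain_lj_limit_matches_closed_form(self):
        """Patches and core off, body LJ at contact: bare LJ spheres."""
        m = PatchyModel(eps_patch=0.0, eps_wca=0.0, body_sigma_factor=1.0,
                        gravity=0.0)
        quat = np.tile(IDENT, (2, 1))
        for r in (1.01, 2 ** (1 / 24), 1.2):
            a = TestTotalEnergy().make_assembly(
                [[4, 4, 3], [4, 4, 3 + r]], quat, m)
            e = total_energy(a, m)
            x = r ** -24.0
            shift = 4 * m.eps_body * (m.r_cut ** -48.0 - m.r_cut ** -24.0)
            assert e == pytest.approx(4 * m.eps_body * (x * x - x) - shift,
                                      rel=1e-9, abs=1e-9)
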