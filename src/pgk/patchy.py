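"""Tetrahedral patchy-particle sedimentation simulator.

The generative model for low-density tetrahedrally coordinated sphere
assemblies: rigid spheres carrying four attractive patches at tetrahedral
angles settle under a tunable gravity in a laterally periodic box with a
repulsive bottom wall.  Interactions (all 2n–n Lennard-Jones with n = 24,
energies in k_BT):

* patch–patch attraction, well depth eps_patch (default 8), modulated by
  the mutual alignment of the best-facing patches;
* a WCA repulsion (eps 10) acting as the excluded-volume core between
  bodies and as the bottom wall;
* a body–body LJ, well depth eps_body (default 3), evaluated at the
  sphere-radius length scale, where it is negligible at contact — all
  non-patch contacts are effectively repulsive, which is what lets the
  low-density tetrahedral network form instead of a dense sticky liquid.
  (Setting body_sigma_factor = 1 moves this term's minimum to contact,
  recovering a uniformly sticky sphere.)

sigma is the centre–centre contact distance (= particle diameter,
default 210 nm); internally everything is reduced (sigma = 1, k_BT = 1,
m = 1) and converted to nm only at the interfaces.  Integration is BAOAB
Langevin for translation plus a quaternion analogue for rotation; at zero
friction the scheme reduces to velocity Verlet and conserves energy, which
``run_langevin`` verifies with a short NVE probe before production.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from scipy.spatial import cKDTree
from scipy.spatial.transform import Rotation

from pgk import _patchy_kernels as _k
from pgk.assembly import SphereAssembly

__all__ = ["PatchyModel", "SimSettings", "radial_potential",
           "patch_alignment_factor", "total_energy", "run_langevin",
           "equilibrate_to_density", "make_settling_start"]

_TET_AXES = np.array([[1, 1, 1], [1, -1, -1], [-1, 1, -1], [-1, -1, 1]],
                     dtype=float) / math.sqrt(3.0)


@dataclass
class PatchyModel:
    """Interaction model of the tetrahedral patchy spheres.

    sigma : centre–centre contact distance, nm (equals the diameter)
    n_exp : LJ steepness (2n–n form), even, default 24
    eps_patch, eps_body, eps_wca : well depths in k_BT
    body_sigma_factor : length scale of the body–body LJ relative to the
        contact distance.  The default 0.5 is the sphere radius, which
        makes the body term negligible at contact so that non-patch
        contacts are purely repulsive (the WCA core, eps_wca, provides
        the excluded volume); 1.0 instead places the body-term minimum
        at contact, giving a uniformly sticky sphere
    patch_axes : 4 unit vectors in the body frame at tetrahedral angles
    patch_halfwidth : angular width delta of the patch modulation, degrees
    gravity : downward force per particle, k_BT/sigma (reduced)
    temperature : k_BT, fixed at 1 in reduced units
    """

    sigma: float = 210.0
    n_exp: int = 24
    eps_patch: float = 8.0
    eps_body: float = 3.0
    eps_wca: float = 10.0
    body_sigma_factor: float = 0.5
    patch_axes: np.ndarray = field(default_factory=lambda: _TET_AXES.copy())
    patch_halfwidth: float = 30.0
    gravity: float = 0.0
    temperature: float = 1.0
    r_cut: float = 1.5          # pair cutoff, reduced

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if self.n_exp < 2 or self.n_exp % 2:
            raise ValueError("n_exp must be even and >= 2")
        for name in ("eps_patch", "eps_body", "eps_wca"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")
        if not 0 < self.body_sigma_factor <= 1.0:
            raise ValueError("body_sigma_factor must be in (0, 1]")
        self.patch_axes = np.asarray(self.patch_axes, dtype=float)
        if self.patch_axes.shape != (4, 3):
            raise ValueError("patch_axes must be 4 unit 3-vectors")
        norms = np.linalg.norm(self.patch_axes, axis=1)
        if np.any(np.abs(norms - 1) > 1e-9):
            raise ValueError("patch axes must be unit vectors")
        dots = self.patch_axes @ self.patch_axes.T
        off = dots[~np.eye(4, dtype=bool)]
        if np.any(np.abs(off - (-1.0 / 3.0)) > 1e-9):
            raise ValueError("patch axes must sit at tetrahedral angles "
                             "(pairwise cos = -1/3)")
        if not 0 < self.patch_halfwidth < 90:
            raise ValueError("patch_halfwidth must be in (0, 90) degrees")

    @property
    def delta_rad(self) -> float:
        return math.radians(self.patch_halfwidth)

    @property
    def r_min_reduced(self) -> float:
        """Location of the pair-potential minimum: 2^{1/n} sigma."""
        return 2.0 ** (1.0 / self.n_exp)


@dataclass
class SimSettings:
    """Integrator parameters (reduced units)."""

    dt: float = 0.002
    steps: int = 10_000
    friction: float = 1.0
    friction_rot: float = 0.3
    seed: int = 0
    snapshot_stride: int = 0     # 0: only the final state
    neighbor_rebuild: int = 25
    skin: float = 0.32
    validate_dt: bool = True

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.steps < 1:
            raise ValueError("steps must be >= 1")


# ---------------------------------------------------------------------------
# Potentials (physical-unit interface)
# ---------------------------------------------------------------------------

def radial_potential(r, kind: str, model: PatchyModel):
    """Radial pair energy U(r) in k_BT for centre distance r in nm.

    kinds: 'patch_lj' and 'body_lj' — the full 2n–n LJ form
    4 eps [(sigma/r)^{2n} - (sigma/r)^n], the patch term at the contact
    length sigma and the body term at body_sigma_factor x sigma; 'wca' —
    the truncated-shifted repulsive branch, exactly 0 for
    r > 2^{1/n} sigma.
    """
    r = np.asarray(r, dtype=float)
    if np.any(r <= 0):
        raise ValueError("r must be positive")
    x = (model.sigma / r) ** model.n_exp
    if kind == "patch_lj":
        return 4.0 * model.eps_patch * (x * x - x)
    if kind == "body_lj":
        xb = (model.body_sigma_factor * model.sigma / r) ** model.n_exp
        return 4.0 * model.eps_body * (xb * xb - xb)
    if kind == "wca":
        u = 4.0 * model.eps_wca * (x * x - x + 0.25)
        return np.where(r <= model.r_min_reduced * model.sigma, u, 0.0)
    raise ValueError(f"unknown potential kind {kind!r}")


def _alignment_g(theta: float, delta: float) -> float:
    th1, th2 = 2.0 * delta, 3.0 * delta
    if theta >= th2:
        return 0.0
    g = math.exp(-theta * theta / (2.0 * delta * delta))
    if theta > th1:
        u = 0.5 * math.pi * (theta - th1) / (th2 - th1)
        g *= math.cos(u) ** 2
    return g


def patch_alignment_factor(quat_i, quat_j, r_ij, model: PatchyModel) -> float:
    """Mutual patch alignment factor in [0, 1] for a particle pair.

    1 when a patch of i and a patch of j face each other exactly along the
    centre line r_ij (pointing from i to j); decays smoothly to 0 and is
    exactly 0 beyond 3x the halfwidth; symmetric under particle exchange.
    """
    r_ij = np.asarray(r_ij, dtype=float)
    rn = np.linalg.norm(r_ij)
    if rn <= 0:
        raise ValueError("|r_ij| must be positive")
    u = r_ij / rn
    delta = model.delta_rad

    def best(quat, direction):
        rot = Rotation.from_quat(np.roll(np.asarray(quat, float), -1))
        axes = rot.apply(model.patch_axes)
        c = float(np.max(axes @ direction))
        return _alignment_g(math.acos(max(-1.0, min(1.0, c))), delta)

    return best(quat_i, u) * best(quat_j, -u)


# ---------------------------------------------------------------------------
# Reduced-state plumbing
# ---------------------------------------------------------------------------

def _to_reduced(a: SphereAssembly, model: PatchyModel):
    pos = a.positions / model.sigma
    quat = a.orientations
    if quat is None:
        quat = np.tile([1.0, 0, 0, 0], (a.n, 1))
    return np.ascontiguousarray(pos), np.ascontiguousarray(quat.copy())


def _to_assembly(pos, quat, box_red, model: PatchyModel,
                 meta: Optional[dict] = None) -> SphereAssembly:
    sig = model.sigma
    box = np.asarray(box_red, dtype=float).copy()
    # the top is open: grow the stored box if particles bounced above it
    box[2] = max(box[2], float(pos[:, 2].max()) + 1.0)
    a = SphereAssembly(pos * sig, np.full(len(pos), sig / 2.0),
                       box * sig, np.array([True, True, False]),
                       orientations=quat.copy(), meta=dict(meta or {}))
    return a.wrapped()


def _pair_candidates(pos, lx, ly, cutoff):
    """Laterally periodic candidate pairs within cutoff (z non-periodic)."""
    zspan = float(pos[:, 2].max()) + 2.0 * cutoff + 1.0
    wrapped = pos.copy()
    wrapped[:, 0] %= lx
    wrapped[:, 1] %= ly
    boxsize = np.array([lx, ly, max(zspan, cutoff * 4.0)])
    tree = cKDTree(wrapped, boxsize=boxsize)
    return tree.query_pairs(r=cutoff, output_type="ndarray").astype(np.int64)


def _forces(pos, quat, pairs, lx, ly, model: PatchyModel):
    n = len(pos)
    patches = np.empty((n, 4, 3))
    _k.rotate_patches(quat, model.patch_axes, patches)
    forces = np.empty((n, 3))
    torques = np.empty((n, 3))
    delta = model.delta_rad
    e = _k.compute_forces(
        pos, patches, pairs, lx, ly,
        model.eps_patch, model.eps_body, model.body_sigma_factor,
        model.eps_wca, float(model.n_exp), model.r_cut,
        1.0 / (2.0 * delta * delta), 2.0 * delta, 3.0 * delta,
        model.gravity, model.eps_wca, 24.0, 0.5,
        forces, torques)
    return e, forces, torques


def total_energy(a: SphereAssembly, model: PatchyModel) -> float:
    """Total potential energy (k_BT): pair terms + wall + gravity.

    Pair energy = WCA core + alignment-modulated patch LJ + body LJ at
    body_sigma_factor x sigma, truncated and shifted at the cutoff.
    Overlapping particles (r < 0.5 sigma) trigger a warning but the energy
    is returned (finite by construction of the 2n-n form at r > 0).
    """
    import warnings

    pos, quat = _to_reduced(a, model)
    if not (a.periodic[0] and a.periodic[1]) or a.periodic[2]:
        raise ValueError("expected laterally periodic box with walled z")
    lx, ly = a.box[0] / model.sigma, a.box[1] / model.sigma
    pairs = _pair_candidates(pos, lx, ly, model.r_cut)
    if len(pairs):
        dr = pos[pairs[:, 0]] - pos[pairs[:, 1]]
        dr[:, 0] -= lx * np.round(dr[:, 0] / lx)
        dr[:, 1] -= ly * np.round(dr[:, 1] / ly)
        d = np.linalg.norm(dr, axis=1)
        if np.any(d < 0.5):
            warnings.warn("overlapping particles (r < 0.5 sigma)", stacklevel=2)
    e, _, _ = _forces(pos, quat, pairs, lx, ly, model)
    return float(e)


# ---------------------------------------------------------------------------
# Integration
# ---------------------------------------------------------------------------

_MASS = 1.0
_INERTIA = 0.1  # solid sphere: (2/5) m (sigma/2)^2


class SimulationUnstable(RuntimeError):
    def __init__(self, step: int, message: str):
        super().__init__(f"instability at step {step}: {message}")
        self.step = step


def _integrate(pos, quat, vel, angvel, model, settings, n_steps, lx, ly,
               rng, friction=None):
    """Advance n_steps of BAOAB; mutates state arrays; returns final PE.

    The inner loop (cell-list pair build + integration) runs in compiled
    chunks of ``neighbor_rebuild`` steps; the skin must cover the drift
    within a chunk.  The lateral box must span at least 3 cells
    (>= 3 x (r_cut + skin) sigma).
    """
    dt = settings.dt
    gamma = settings.friction if friction is None else friction
    gamma_r = settings.friction_rot if friction is None else friction
    kT = model.temperature
    c1 = math.exp(-gamma * dt)
    c2 = math.sqrt((1 - c1 * c1) * kT / _MASS) if gamma > 0 else 0.0
    c1r = math.exp(-gamma_r * dt)
    c2r = math.sqrt((1 - c1r * c1r) * kT / _INERTIA) if gamma_r > 0 else 0.0
    cutoff = model.r_cut + settings.skin
    if lx < 3 * cutoff or ly < 3 * cutoff:
        raise ValueError(f"lateral box must be >= {3 * cutoff:.2f} sigma "
                         "for the cell list")
    n = len(pos)
    delta = model.delta_rad
    pairs_buf = np.empty((max(n * 60, 20_000), 2), dtype=np.int64)
    patches = np.empty((n, 4, 3))
    forces = np.empty((n, 3))
    torques = np.empty((n, 3))
    zeros = None
    e = 0.0
    done = 0
    while done < n_steps:
        chunk = min(settings.neighbor_rebuild, n_steps - done)
        if c2 > 0 or c2r > 0:
            noise_t = rng.standard_normal((chunk, n, 3))
            noise_r = rng.standard_normal((chunk, n, 3))
        else:
            if zeros is None or zeros.shape[0] < chunk:
                zeros = np.zeros((chunk, n, 3))
            noise_t = noise_r = zeros
        e, npairs = _k.integrate_chunk(
            pos, quat, vel, angvel, model.patch_axes, chunk, dt,
            c1, c2, c1r, c2r, noise_t, noise_r,
            lx, ly, model.eps_patch, model.eps_body,
            model.body_sigma_factor, model.eps_wca, float(model.n_exp),
            model.r_cut, 1.0 / (2 * delta * delta), 2 * delta, 3 * delta,
            model.gravity, model.eps_wca, 24.0, 0.5,
            settings.skin, pairs_buf, patches, forces, torques,
            _MASS, _INERTIA)
        if npairs < 0:
            pairs_buf = np.empty((pairs_buf.shape[0] * 2, 2), dtype=np.int64)
            continue
        done += chunk
        if not np.isfinite(e) or not np.all(np.isfinite(pos)):
            raise SimulationUnstable(done, "non-finite energy or positions")
    return e


def _kinetic(vel, angvel):
    return (0.5 * _MASS * float(np.sum(vel ** 2))
            + 0.5 * _INERTIA * float(np.sum(angvel ** 2)))


def _nve_probe(pos, quat, vel, angvel, model, settings, lx, ly) -> float:
    """Relative energy drift of a 100-step zero-friction run from this state."""
    p, q = pos.copy(), quat.copy()
    v, w = vel.copy(), angvel.copy()
    rng = np.random.default_rng(0)
    pairs = _pair_candidates(p, lx, ly, model.r_cut + settings.skin)
    e0, _, _ = _forces(p, q, pairs, lx, ly, model)
    tot0 = e0 + _kinetic(v, w)
    e1 = _integrate(p, q, v, w, model, settings, 100, lx, ly, rng, friction=0.0)
    tot1 = e1 + _kinetic(v, w)
    scale = max(abs(tot0), _kinetic(vel, angvel), 1.0)
    return abs(tot1 - tot0) / scale


def run_langevin(initial: SphereAssembly, model: PatchyModel,
                 settings: SimSettings) -> List[SphereAssembly]:
    """Langevin dynamics from ``initial``; returns snapshots (final included).

    The box must be laterally periodic with a walled z axis (bottom WCA
    wall at z = 0, open top).  Deterministic given ``settings.seed``.  When
    ``validate_dt`` is on, a 100-step zero-friction probe checks that the
    time step conserves energy to < 1% before production starts.
    """
    if not (initial.periodic[0] and initial.periodic[1]) or initial.periodic[2]:
        raise ValueError("box must be periodic in x, y and walled in z")
    pos, quat = _to_reduced(initial, model)
    lx, ly = initial.box[0] / model.sigma, initial.box[1] / model.sigma
    box_red = initial.box / model.sigma
    rng = np.random.default_rng(settings.seed)
    kT = model.temperature
    vel = rng.normal(0.0, math.sqrt(kT / _MASS), pos.shape)
    angvel = rng.normal(0.0, math.sqrt(kT / _INERTIA), pos.shape)

    if settings.validate_dt:
        drift = _nve_probe(pos, quat, vel, angvel, model, settings, lx, ly)
        if drift > 0.01:
            raise ValueError(
                f"dt = {settings.dt} fails the NVE check "
                f"(relative drift {drift:.2%} over 100 steps); reduce dt")

    stride = settings.snapshot_stride or settings.steps
    snaps: List[SphereAssembly] = []
    done = 0
    while done < settings.steps:
        n = min(stride, settings.steps - done)
        e = _integrate(pos, quat, vel, angvel, model, settings, n, lx, ly, rng)
        done += n
        snaps.append(_to_assembly(pos, quat, box_red, model,
                                  meta={"step": done, "seed": settings.seed,
                                        "potential_energy_kT": float(e),
                                        "gravity": model.gravity}))
    return snaps


# ---------------------------------------------------------------------------
# Sedimentation to a target density
# ---------------------------------------------------------------------------

def make_settling_start(n: int, model: PatchyModel, lateral: float = 8.0,
                        seed: int = 0, spacing: float = 1.3,
                        z0: float = 1.0) -> SphereAssembly:
    """A dilute jittered grid of n particles above the bottom wall.

    ``lateral`` is the periodic box edge in sigma; particles occupy a
    simple-cubic grid with the given spacing (sigma) starting at height z0,
    with random orientations.  The box height adapts to hold them all.
    """
    rng = np.random.default_rng(seed)
    per_layer = int(lateral / spacing) ** 2
    n_layers = int(np.ceil(n / per_layer))
    side = int(lateral / spacing)
    pts = []
    for layer in range(n_layers):
        for iy in range(side):
            for ix in range(side):
                if len(pts) >= n:
                    break
                pts.append([(ix + 0.5) * spacing, (iy + 0.5) * spacing,
                            z0 + layer * spacing])
    pos = np.asarray(pts) + rng.uniform(-0.08, 0.08, (n, 3))
    pos[:, 2] = np.maximum(pos[:, 2], 0.7)
    height = pos[:, 2].max() + 3.0
    quat = Rotation.random(n, random_state=np.random.RandomState(seed)).as_quat()
    quat = np.roll(quat, 1, axis=1)  # scipy xyzw -> wxyz
    sig = model.sigma
    return SphereAssembly(pos * sig, np.full(n, sig / 2.0),
                          np.array([lateral, lateral, height]) * sig,
                          np.array([True, True, False]),
                          orientations=quat, meta={"seed": seed})


def settled_bulk_phi(a: SphereAssembly) -> float:
    """Packing fraction in the bulk slab of a sediment (wall and free
    surface layers excluded)."""
    from pgk.contacts import bulk_slab, packing_fraction

    z_lo, z_hi = bulk_slab(a)
    region = (np.array([0.0, 0.0, z_lo]), np.array([a.box[0], a.box[1], z_hi]))
    est = packing_fraction(a, method="analytic", region=region,
                           on_overlap="ignore")
    return float(est)


def equilibrate_to_density(model: PatchyModel, target_phi: float,
                           settings: SimSettings, n: int = 1080,
                           lateral: float = 8.0, tol: float = 0.02,
                           g_bounds: Tuple[float, float] = (0.05, 20.0),
                           max_iters: int = 7,
                           initial_g: Optional[float] = None):
    """Adjust gravity until the settled bed equilibrates at ``target_phi``.

    Runs the full sedimentation (settings.steps Langevin steps from a
    dilute start) at trial gravities, measuring the bulk packing fraction
    of the final bed; bisection on log g exploits the monotone increase of
    bed density with gravity.  Returns (assembly, achieved_phi, gravity).

    Raises when the target is outside the achievable bracket.
    """
    if not 0 < target_phi < 0.74:
        raise ValueError("target_phi must be in (0, 0.74)")

    history = {}

    def run_at(g: float):
        m = PatchyModel(**{**model.__dict__, "gravity": g,
                           "patch_axes": model.patch_axes.copy()})
        start = make_settling_start(n, m, lateral=lateral, seed=settings.seed)
        # measure the settled density as the mean over the last few
        # snapshots, damping single-frame fluctuations of the bed surface
        s = SimSettings(**{**settings.__dict__,
                           "snapshot_stride": max(settings.steps // 20, 1)})
        snaps = run_langevin(start, m, s)
        final = snaps[-1]
        phi = float(np.mean([settled_bulk_phi(f) for f in snaps[-3:]]))
        history[g] = phi
        final.meta.update({"gravity": g, "bulk_phi": phi})
        return final, phi

    g = initial_g if initial_g is not None else (model.gravity or 1.0)
    g = min(max(g, g_bounds[0]), g_bounds[1])
    final, phi = run_at(g)
    if abs(phi - target_phi) <= tol:
        return final, phi, g

    lo, hi = g_bounds
    # expand/bisect on log g assuming phi grows with g
    g_lo, g_hi = None, None
    for gk, pk in history.items():
        if pk < target_phi:
            g_lo = gk if g_lo is None else max(g_lo, gk)
        else:
            g_hi = gk if g_hi is None else min(g_hi, gk)
    for _ in range(max_iters):
        if g_lo is None:
            g = max(min(history) / 4.0, lo)
            if g in history:
                break
        elif g_hi is None:
            g = min(max(history) * 4.0, hi)
            if g in history:
                break
        else:
            g = math.sqrt(g_lo * g_hi)
        final, phi = run_at(g)
        if abs(phi - target_phi) <= tol:
            return final, phi, g
        if phi < target_phi:
            g_lo = g
        else:
            g_hi = g
        if g_lo is not None and g_hi is not None and g_hi / g_lo < 1.05:
            break
    achieved = {round(k, 4): round(v, 4) for k, v in history.items()}
    raise RuntimeError(
        f"target phi = {target_phi} unreachable within gravity bracket "
        f"{g_bounds}; achieved {achieved}")
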