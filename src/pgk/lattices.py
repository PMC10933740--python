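"""Reference lattices and jammed packings.

``build_lattice`` produces ideal periodic sphere crystals (sc, fcc, bcc,
hcp, diamond) used as reference structures for contact counting and
bond-orientational-order classification.  ``generate_jammed_packing``
produces maximally-random-jammed-style packings by a soft-sphere
growth-and-quench protocol: particles are inflated stepwise and the
harmonic overlap energy is minimised (FIRE) after each step; the jamming
point is bracketed by bisection on the packing fraction.  Monodisperse
packings jam at phi ~ 0.64 with ~6 contacts per non-rattler particle.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from pgk.assembly import SphereAssembly

__all__ = ["LatticeSpec", "JamSpec", "JammingError",
           "build_lattice", "generate_jammed_packing", "perturb_assembly"]


# ---------------------------------------------------------------------------
# Ideal lattices
# ---------------------------------------------------------------------------

# fractional bases in the conventional (sc/fcc/bcc/diamond, cubic) or
# orthorhombic (hcp) cell; nn = nearest-neighbour distance / lattice
# parameter; offset shifts sites off the cell faces (pure translation,
# physically irrelevant under periodic boundaries but convenient for
# voxelisation fixtures)
_FCC_BASE = [(0, 0, 0), (0, .5, .5), (.5, 0, .5), (.5, .5, 0)]
_LATTICES = {
    "sc":      {"basis": [(0, 0, 0)], "cell": (1, 1, 1), "nn": 1.0,
                "offset": (.5, .5, .5)},
    "fcc":     {"basis": _FCC_BASE, "cell": (1, 1, 1), "nn": 1 / np.sqrt(2),
                "offset": (.25, .25, .25)},
    "bcc":     {"basis": [(0, 0, 0), (.5, .5, .5)], "cell": (1, 1, 1),
                "nn": np.sqrt(3) / 2, "offset": (.25, .25, .25)},
    "diamond": {"basis": _FCC_BASE + [(x + .25, y + .25, z + .25)
                                      for x, y, z in _FCC_BASE],
                "cell": (1, 1, 1), "nn": np.sqrt(3) / 4,
                "offset": (.125, .125, .125)},
    # orthorhombic 4-site cell so the periodic box stays rectangular
    "hcp":     {"basis": [(0, 0, 0), (.5, .5, 0), (.5, 5 / 6, .5), (0, 1 / 3, .5)],
                "cell": (1.0, np.sqrt(3), np.sqrt(8 / 3)), "nn": 1.0,
                "offset": (.25, .25, .25)},
}


@dataclass
class LatticeSpec:
    """Specification of an ideal sphere crystal.

    ``lattice_parameter`` is the conventional-cell edge a (nm); in
    'touching' mode the sphere radius is half the nearest-neighbour
    distance, so nearest neighbours are in exact contact.
    """

    kind: str
    lattice_parameter: float = 100.0
    repeats: tuple = (3, 3, 3)
    sphere_radius_mode: str = "touching"
    explicit_radius: Optional[float] = None

    def __post_init__(self) -> None:
        if self.kind not in _LATTICES:
            raise ValueError(f"unknown lattice kind {self.kind!r}; "
                             f"choose from {sorted(_LATTICES)}")
        self.repeats = tuple(int(r) for r in self.repeats)
        if len(self.repeats) != 3 or min(self.repeats) < 1:
            raise ValueError("repeats must be three integers >= 1")
        if self.lattice_parameter <= 0:
            raise ValueError("lattice_parameter must be positive")
        if self.sphere_radius_mode not in ("touching", "explicit"):
            raise ValueError("sphere_radius_mode must be 'touching' or 'explicit'")
        if self.sphere_radius_mode == "explicit" and (
                self.explicit_radius is None or self.explicit_radius <= 0):
            raise ValueError("explicit mode needs a positive explicit_radius")

    @property
    def nn_distance(self) -> float:
        return _LATTICES[self.kind]["nn"] * self.lattice_parameter

    @property
    def radius(self) -> float:
        if self.sphere_radius_mode == "touching":
            return 0.5 * self.nn_distance
        return float(self.explicit_radius)


def build_lattice(spec: LatticeSpec) -> SphereAssembly:
    """Build the periodic sphere crystal described by ``spec``.

    The particle count is repeats product x basis size (sc 1, fcc 4, bcc 2,
    hcp 4 per orthorhombic cell, diamond 8).  In touching mode the minimal
    centre-centre distance equals exactly 2 x radius.  An explicit radius
    larger than half the nearest-neighbour distance is an error.
    """
    info = _LATTICES[spec.kind]
    a = spec.lattice_parameter
    cell = np.array(info["cell"]) * a
    basis = (np.array(info["basis"]) + np.array(info["offset"])) * cell
    nx, ny, nz = spec.repeats
    shifts = np.array([(i, j, k) for i in range(nx) for j in range(ny)
                       for k in range(nz)], dtype=float) * cell
    pos = (shifts[:, None, :] + basis[None, :, :]).reshape(-1, 3)
    box = cell * np.array(spec.repeats, dtype=float)
    r = spec.radius
    if r > 0.5 * spec.nn_distance + 1e-9:
        raise ValueError(
            f"explicit radius {r} overlaps neighbours "
            f"(max {0.5 * spec.nn_distance:.6g} for {spec.kind})")
    radii = np.full(len(pos), r)
    return SphereAssembly(pos, radii, box, np.array([True] * 3),
                          meta={"lattice": spec.kind,
                                "lattice_parameter": a,
                                "nn_distance": spec.nn_distance})


def perturb_assembly(a: SphereAssembly, amplitude: float,
                     seed: int) -> SphereAssembly:
    """Displace every centre by an isotropic Gaussian of sd ``amplitude`` nm.

    Radii, box and orientations are unchanged; deterministic given seed.
    """
    if amplitude < 0:
        raise ValueError("amplitude must be >= 0")
    out = a.copy()
    if amplitude > 0:
        rng = np.random.default_rng(seed)
        out.positions = out.positions + rng.normal(0.0, amplitude,
                                                   size=out.positions.shape)
        out = out.wrapped()
    return out


# ---------------------------------------------------------------------------
# Jammed packings (soft-sphere growth and quench)
# ---------------------------------------------------------------------------

@dataclass
class JamSpec:
    """Parameters of the growth-and-quench jamming protocol.

    ``polydispersity`` is the relative sd of the (Gaussian) radius
    distribution; ``phi_step`` the initial growth increment; ``phi_tol``
    the bisection width at which the jamming point is accepted;
    ``force_tol`` the FIRE convergence threshold on the rms residual force
    (in units of the harmonic contact stiffness).
    """

    n: int = 1000
    polydispersity: float = 0.0
    seed: int = 0
    phi_start: float = 0.30
    phi_step: float = 0.01
    phi_tol: float = 2.5e-4
    force_tol: float = 1e-10
    target_phi: Optional[float] = None
    max_minimize_steps: int = 150_000

    def __post_init__(self) -> None:
        if self.n < 4:
            raise ValueError("need at least 4 particles")
        if self.polydispersity < 0:
            raise ValueError("polydispersity must be >= 0")


class JammingError(RuntimeError):
    """Quench failed; carries the last state for diagnosis."""

    def __init__(self, message: str, state: Optional[SphereAssembly] = None):
        super().__init__(message)
        self.state = state


def _pair_list(pos: np.ndarray, cutoff: float) -> np.ndarray:
    tree = cKDTree(pos % 1.0, boxsize=1.0)
    return tree.query_pairs(r=min(cutoff, 0.499), output_type="ndarray")


def _fire_minimize(pos, radii, force_tol, max_steps,
                   e_floor_pp: float = 1e-16):
    """FIRE energy minimisation on the unit periodic box.

    Neighbour lists are rebuilt between numba chunks; the skin (30% of the
    diameter) comfortably covers per-chunk drift at the FIRE step sizes
    used.  Returns (pos, energy, converged).
    """
    from pgk import _fire

    pos = np.ascontiguousarray(pos % 1.0)
    n = len(radii)
    vel = np.zeros_like(pos)
    forces = np.empty_like(pos)
    cutoff = 2.0 * radii.max() * 1.3
    state = np.array([0.02 * radii.min(), 0.1, 0.0])
    dt_max = 0.2 * radii.min()
    chunk = 60
    done = 0
    e = 0.0
    e_hist: list = []
    while done < max_steps:
        pairs = _pair_list(pos, cutoff)
        e, conv = _fire.fire_chunk(pos, vel, forces, radii, pairs, state,
                                   min(chunk, max_steps - done),
                                   dt_max, force_tol, e_floor_pp)
        if conv:
            return pos, e, True
        done += chunk
        # near the jamming point the residual-force tail can decay
        # arbitrarily slowly; a stagnant energy at clearly contact-scale
        # values is force balance for every purpose here
        e_hist.append(e)
        window = max(3000 // chunk, 2)
        if (len(e_hist) > window and e / n > 1e-13
                and abs(e_hist[-1 - window] - e) <= 1e-9 * e):
            return pos, e, True
    return pos, e, False


def _set_phi(radii_unit, phi):
    """Scale unit-mean radii so the packing fraction in the unit box is phi."""
    v1 = np.sum(4.0 / 3.0 * np.pi * radii_unit ** 3)
    return radii_unit * (phi / v1) ** (1.0 / 3.0)


def _overlap_pairs(pos, radii, tol=1e-8):
    pairs = _pair_list(pos, 2.0 * radii.max() * 1.1)
    if len(pairs) == 0:
        return pairs
    dr = pos[pairs[:, 0]] - pos[pairs[:, 1]]
    dr -= np.round(dr)
    d = np.linalg.norm(dr, axis=1)
    sig = radii[pairs[:, 0]] + radii[pairs[:, 1]]
    return pairs[d < sig * (1.0 - tol)]


def _find_rattlers(n, pairs, min_contacts=4):
    """Iteratively prune particles with < min_contacts force-bearing contacts."""
    active = np.ones(n, dtype=bool)
    while True:
        deg = np.zeros(n, dtype=int)
        keep = active[pairs[:, 0]] & active[pairs[:, 1]] if len(pairs) else \
            np.zeros(0, dtype=bool)
        if len(pairs):
            np.add.at(deg, pairs[keep, 0], 1)
            np.add.at(deg, pairs[keep, 1], 1)
        newly = active & (deg < min_contacts)
        if not np.any(newly):
            return ~active, deg
        active &= ~newly


def generate_jammed_packing(spec: JamSpec,
                            box_nm: float = 1000.0) -> SphereAssembly:
    """Generate a jammed soft-sphere packing in a periodic cubic box.

    Particles are grown in packing-fraction steps with a FIRE quench after
    each step; jamming is declared when the quench can no longer relax the
    overlap energy to the floor, and the onset is then bisected to
    ``phi_tol``.  The returned assembly is the marginally jammed state:

    * ``labels`` flag rattlers (label 1) vs force-bearing particles (0)
    * ``meta`` records phi, mean contact number of non-rattlers, seed.

    With ``target_phi`` set, the packing is grown to that fraction only and
    must jam there, else :class:`JammingError` is raised.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n
    r_unit = np.ones(n)
    if spec.polydispersity > 0:
        r_unit = rng.normal(1.0, spec.polydispersity, n)
        r_unit = np.clip(r_unit, 0.3, None)
    pos = rng.random((n, 3))

    e_floor = 1e-16  # per particle: below -> unjammed (overlaps removable)

    def quench(pos, phi):
        radii = _set_phi(r_unit, phi)
        pos, e, ok = _fire_minimize(pos, radii, spec.force_tol,
                                    spec.max_minimize_steps)
        epp = e / n
        if not ok and epp <= 100.0 * e_floor:
            # neither force-balanced nor clearly jammed: the residual
            # energy sits in the ambiguous band just above the floor
            raise JammingError(
                f"quench at phi={phi:.4f} did not reach force balance or "
                f"the energy floor within {spec.max_minimize_steps} steps "
                f"(residual {epp:.2e}/particle)",
                _as_assembly(pos, radii, box_nm, spec, None))
        # a quench that still carries contact-scale energy after the full
        # step budget is jammed; the slow residual-force tail near the
        # jamming point does not change the classification
        return pos, radii, epp

    # initial relaxation at a dilute fraction
    pos, radii, epp = quench(pos, spec.phi_start)

    if spec.target_phi is not None:
        pos, radii, epp = quench(pos, spec.target_phi)
        if epp < e_floor:
            raise JammingError(
                f"requested phi={spec.target_phi} is below the jamming "
                f"density (residual energy {epp:.2e}/particle)",
                _as_assembly(pos, radii, box_nm, spec, None))
        phi_lo = phi_hi = spec.target_phi
    else:
        phi = spec.phi_start
        phi_lo, phi_hi = phi, None
        guard = 0
        while phi_hi is None:
            phi += spec.phi_step
            guard += 1
            if guard > 80:
                raise JammingError("growth failed to reach jamming",
                                   _as_assembly(pos, radii, box_nm, spec, None))
            pos, radii, epp = quench(pos, phi)
            if epp > e_floor:
                phi_hi = phi
            else:
                phi_lo = phi
        while phi_hi - phi_lo > spec.phi_tol:
            phi = 0.5 * (phi_lo + phi_hi)
            pos, radii, epp = quench(pos, phi)
            if epp > e_floor:
                phi_hi = phi
            else:
                phi_lo = phi
        # finish on the jammed side of the bracket; the jamming point can
        # drift upward as the configuration anneals, so re-grow in small
        # steps if the final quench relaxed
        pos, radii, epp = quench(pos, phi_hi)
        regrow = 0
        while epp <= e_floor:
            regrow += 1
            if regrow > 60:
                raise JammingError("bisection lost the jammed branch",
                                   _as_assembly(pos, radii, box_nm, spec, None))
            phi_hi += spec.phi_tol
            pos, radii, epp = quench(pos, phi_hi)

    # measure contacts at a slight fixed overcompression beyond the onset,
    # so every force-bearing contact has a resolvable overlap
    pos, radii, epp = quench(pos, phi_hi + spec.phi_tol)
    pairs = _overlap_pairs(pos, radii)
    rattler, deg = _find_rattlers(n, pairs)
    nz = ~rattler
    mean_contacts = float(2.0 * np.sum([1 for p in pairs
                                        if nz[p[0]] and nz[p[1]]])
                          / max(np.sum(nz), 1))
    out = _as_assembly(pos, radii, box_nm, spec, rattler)
    out.meta.update({
        "phi": float(np.sum(4 / 3 * np.pi * radii ** 3)),
        "mean_contacts_nonrattler": mean_contacts,
        "n_rattlers": int(np.sum(rattler)),
        "seed": spec.seed,
    })
    return out


def _as_assembly(pos, radii, box_nm, spec, rattler):
    labels = None if rattler is None else rattler.astype(int)
    return SphereAssembly(pos * box_nm, radii * box_nm,
                          np.full(3, float(box_nm)), np.array([True] * 3),
                          labels=labels, meta={"seed": spec.seed})
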