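"""Contact-graph construction, touching-neighbour statistics, packing fraction.

The touching criterion follows the tomography convention: particles i and j
are in contact when the (minimum-image) centre distance satisfies

    d_ij <= r_i + r_j + gap_tol

with a default gap tolerance of 15 nm, the voxel side length of the emulated
tomograms.  ``n_touch`` is the degree of a particle in this graph.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy.spatial import cKDTree

from pgk.assembly import SphereAssembly

__all__ = ["ContactGraph", "PackingSummary", "PhiEstimate",
           "contact_graph", "n_touch_distribution", "packing_fraction",
           "bulk_slab", "select_bulk"]

DEFAULT_GAP_NM = 15.0


@dataclass
class ContactGraph:
    """Symmetric particle contact relation at a given gap tolerance."""

    n: int
    edges: np.ndarray          # (E, 2) int array, i < j, no self-edges
    gap_tol: float

    def __post_init__(self) -> None:
        self.edges = np.asarray(self.edges, dtype=int).reshape(-1, 2)
        if np.any(self.edges[:, 0] == self.edges[:, 1]):
            raise ValueError("self-edges are not allowed")
        lo = np.minimum(self.edges[:, 0], self.edges[:, 1])
        hi = np.maximum(self.edges[:, 0], self.edges[:, 1])
        self.edges = np.unique(np.column_stack([lo, hi]), axis=0)

    @property
    def degrees(self) -> np.ndarray:
        d = np.zeros(self.n, dtype=int)
        if len(self.edges):
            np.add.at(d, self.edges[:, 0], 1)
            np.add.at(d, self.edges[:, 1], 1)
        return d

    def neighbors(self, i: int) -> np.ndarray:
        e = self.edges
        return np.concatenate([e[e[:, 0] == i, 1], e[e[:, 1] == i, 0]])

    def neighbor_lists(self) -> list:
        out = [[] for _ in range(self.n)]
        for i, j in self.edges:
            out[i].append(j)
            out[j].append(i)
        return [np.asarray(v, dtype=int) for v in out]


@dataclass
class PackingSummary:
    """Ensemble summary: volume fraction + n_touch statistics."""

    n: int
    gap_tol: float
    n_touch_mean: float
    n_touch_sd: float
    n_touch_mode: int
    histogram: dict
    phi: Optional[float] = None
    meta: dict = field(default_factory=dict)

    def as_dict(self) -> dict:
        return {
            "N": self.n, "gap_tol_nm": self.gap_tol, "phi": self.phi,
            "n_touch_mean": self.n_touch_mean, "n_touch_sd": self.n_touch_sd,
            "n_touch_mode": self.n_touch_mode,
            "histogram": {str(k): int(v) for k, v in self.histogram.items()},
            **self.meta,
        }


@dataclass
class PhiEstimate:
    phi: float
    se: Optional[float]
    method: str

    def __float__(self) -> float:
        return float(self.phi)


def _with_ghosts(a: SphereAssembly, cutoff: float):
    """Positions plus periodic ghost images within `cutoff` of the faces.

    Returns (points, index) where index maps each point back to its
    original particle.  Handles per-axis periodicity, which cKDTree's
    boxsize cannot.
    """
    pos = a.wrapped().positions
    pts = pos
    idx = np.arange(a.n)
    for ax in range(3):
        if not a.periodic[ax]:
            continue
        L = a.box[ax]
        lo = pts[:, ax] < cutoff
        hi = pts[:, ax] > L - cutoff
        shifted_lo = pts[lo].copy()
        shifted_lo[:, ax] += L
        shifted_hi = pts[hi].copy()
        shifted_hi[:, ax] -= L
        pts = np.vstack([pts, shifted_lo, shifted_hi])
        idx = np.concatenate([idx, idx[lo], idx[hi]])
    return pts, idx


def contact_graph(a: SphereAssembly, gap_tol: float = DEFAULT_GAP_NM) -> ContactGraph:
    """Build the touching-neighbour graph d_ij <= r_i + r_j + gap_tol.

    Uses a k-d tree with periodic ghost images, so the expected cost is
    O(N) for homogeneous assemblies; agrees exactly with the all-pairs
    brute force.
    """
    if gap_tol < 0:
        raise ValueError("gap_tol must be >= 0")
    rmax = float(np.max(a.radii))
    cutoff = 2.0 * rmax + gap_tol
    if np.any(a.box[a.periodic] < 2.0 * cutoff):
        # tiny periodic boxes: fall back to explicit minimum-image all-pairs
        return _contact_graph_bruteforce(a, gap_tol)
    pts, idx = _with_ghosts(a, cutoff)
    tree = cKDTree(pts)
    pairs = tree.query_pairs(r=cutoff, output_type="ndarray")
    if len(pairs) == 0:
        return ContactGraph(a.n, np.empty((0, 2), dtype=int), gap_tol)
    d = np.linalg.norm(pts[pairs[:, 0]] - pts[pairs[:, 1]], axis=1)
    i = idx[pairs[:, 0]]
    j = idx[pairs[:, 1]]
    keep = (d <= a.radii[i] + a.radii[j] + gap_tol + 1e-12) & (i != j)
    return ContactGraph(a.n, np.column_stack([i[keep], j[keep]]), gap_tol)


def _contact_graph_bruteforce(a: SphereAssembly, gap_tol: float) -> ContactGraph:
    pos = a.wrapped().positions
    ii, jj = np.triu_indices(a.n, k=1)
    dr = a.minimum_image(pos[ii] - pos[jj])
    d = np.linalg.norm(dr, axis=1)
    keep = d <= a.radii[ii] + a.radii[jj] + gap_tol + 1e-12
    return ContactGraph(a.n, np.column_stack([ii[keep], jj[keep]]), gap_tol)


def n_touch_distribution(g: ContactGraph,
                         subset: Optional[np.ndarray] = None) -> PackingSummary:
    """Integer histogram, mean ± sd and mode of the contact-number degrees.

    ``subset`` restricts the statistics to the given particle indices (used
    for bulk-only statistics in sediments); the mean over all particles
    equals 2|E|/N exactly.
    """
    deg = g.degrees
    if subset is not None:
        deg = deg[np.asarray(subset, dtype=int)]
    if len(deg) == 0:
        raise ValueError("empty particle subset")
    vals, counts = np.unique(deg, return_counts=True)
    hist = {int(v): int(c) for v, c in zip(vals, counts)}
    mode = int(vals[np.argmax(counts)])
    return PackingSummary(
        n=len(deg), gap_tol=g.gap_tol,
        n_touch_mean=float(np.mean(deg)), n_touch_sd=float(np.std(deg)),
        n_touch_mode=mode, histogram=hist)


# ---------------------------------------------------------------------------
# Packing fraction
# ---------------------------------------------------------------------------

def _cap_volume(r: float, h: float) -> float:
    """Volume of a spherical cap of height h cut from a sphere of radius r."""
    h = min(max(h, 0.0), 2.0 * r)
    return np.pi * h * h * (3.0 * r - h) / 3.0


def _axis_kept_fraction(x: float, r: float, lo: float, hi: float,
                        periodic: bool, L: float):
    """Clipped volume bookkeeping for one axis.

    Returns (cap_volume_lost_at_faces_for_unit_sphere_radius_r, clipped_flag)
    or None when the sphere lies entirely outside the slab on this axis.
    A periodic axis whose slab spans the whole box never clips (the sphere
    wraps around instead).
    """
    if periodic:
        if hi - lo >= L - 1e-9:
            return 0.0, False
        # partial slab on a periodic axis: use the image of x nearest the
        # slab midpoint, then clip as if walled (exact while slab >> 2r)
        mid = 0.5 * (lo + hi)
        x = x - L * np.round((x - mid) / L)
    if x <= lo - r or x >= hi + r:
        return None
    lost = 0.0
    clipped = False
    if x - lo < r:
        lost += _cap_volume(r, r - (x - lo))
        clipped = True
    if hi - x < r:
        lost += _cap_volume(r, r - (hi - x))
        clipped = True
    return lost, clipped


def _analytic_phi(a: SphereAssembly, lo: np.ndarray, hi: np.ndarray) -> float:
    """Sum of sphere volumes clipped to the axis-aligned region [lo, hi].

    Face clipping uses exact spherical-cap corrections, which is exact as
    long as no sphere is cut by faces of two different axes at once (no
    edge/corner intersections); that situation raises, directing the caller
    to the Monte-Carlo estimator.
    """
    ext = hi - lo
    if 2.0 * float(a.radii.max()) >= float(ext.min()):
        raise ValueError("region thinner than a sphere diameter; use voxel_mc")
    pos = a.wrapped().positions
    total = 0.0
    for p, r in zip(pos, a.radii):
        v = 4.0 / 3.0 * np.pi * r ** 3
        clipped_axes = 0
        outside = False
        for ax in range(3):
            res = _axis_kept_fraction(p[ax], r, lo[ax], hi[ax],
                                      bool(a.periodic[ax]), a.box[ax])
            if res is None:
                outside = True
                break
            lost, clipped = res
            v -= lost
            clipped_axes += int(clipped)
        if outside:
            continue
        if clipped_axes > 1:
            raise ValueError("sphere cut by an edge/corner of the region; "
                             "use voxel_mc")
        total += max(v, 0.0)
    return total / float(np.prod(ext))


def _has_overlaps(a: SphereAssembly) -> bool:
    g = contact_graph(a, gap_tol=0.0)
    if len(g.edges) == 0:
        return False
    pos = a.wrapped().positions
    dr = a.minimum_image(pos[g.edges[:, 0]] - pos[g.edges[:, 1]])
    d = np.linalg.norm(dr, axis=1)
    rsum = a.radii[g.edges[:, 0]] + a.radii[g.edges[:, 1]]
    return bool(np.any(d < rsum - 1e-9))


def packing_fraction(a: SphereAssembly, method: str = "analytic",
                     region: Optional[tuple] = None,
                     samples: int = 50_000,
                     rng: Optional[np.random.Generator] = None,
                     on_overlap: str = "warn_mc") -> PhiEstimate:
    """Volume fraction of sphere material in the box or a sub-region.

    method 'analytic': exact sum of clipped sphere volumes (spherical-cap
    face corrections).  Falls back to 'voxel_mc' with a warning if spheres
    overlap, since overlap volume would be double-counted; pass
    ``on_overlap='ignore'`` to keep the analytic sum when overlaps are
    known to be shallow (e.g. thermal compressions in a simulation frame).

    method 'voxel_mc': Monte-Carlo point sampling; returns the estimate with
    its binomial standard error.

    region: optional (lo, hi) corner pair, nm, inside the box.
    """
    if region is None:
        lo = np.zeros(3)
        hi = a.box.astype(float)
    else:
        lo = np.asarray(region[0], dtype=float)
        hi = np.asarray(region[1], dtype=float)
        if np.any(lo < -1e-9) or np.any(hi > a.box + 1e-9) or np.any(hi <= lo):
            raise ValueError("region must be a non-empty sub-box of the assembly box")
    if method == "analytic":
        if on_overlap != "ignore" and _has_overlaps(a):
            warnings.warn("overlapping spheres: analytic phi would double-count; "
                          "falling back to voxel_mc", stacklevel=2)
            return packing_fraction(a, "voxel_mc", region, samples, rng)
        try:
            return PhiEstimate(_analytic_phi(a, lo, hi), None, "analytic")
        except ValueError as exc:
            if "edge/corner" not in str(exc):
                raise
            warnings.warn(f"{exc}; falling back to voxel_mc", stacklevel=2)
            return packing_fraction(a, "voxel_mc", region, samples, rng)
    if method == "voxel_mc":
        rng = rng or np.random.default_rng(0)
        pts = rng.uniform(lo, hi, size=(samples, 3))
        rmax = float(a.radii.max())
        gpts, gidx = _with_ghosts(a, rmax if np.any(a.periodic) else 0.0)
        tree = cKDTree(gpts)
        # nearest sphere surfaces: a point is inside material if its distance
        # to some centre is below that sphere's radius
        inside = np.zeros(samples, dtype=bool)
        neigh = tree.query_ball_point(pts, r=rmax)
        for k, cand in enumerate(neigh):
            for c in cand:
                if np.linalg.norm(pts[k] - gpts[c]) < a.radii[gidx[c]]:
                    inside[k] = True
                    break
        phi = float(np.mean(inside))
        se = float(np.sqrt(max(phi * (1 - phi), 1e-12) / samples))
        return PhiEstimate(phi, se, "voxel_mc")
    raise ValueError(f"unknown method {method!r}")


# ---------------------------------------------------------------------------
# Bulk selection for sediments
# ---------------------------------------------------------------------------

def bulk_slab(a: SphereAssembly, margin_diameters: float = 1.5,
              coverage: float = 0.98) -> tuple:
    """(z_lo, z_hi) of the bulk of a sediment along the walled z axis.

    Excludes `margin_diameters` mean diameters above the bottom wall and
    below the free surface; the surface is taken as the `coverage` quantile
    of particle heights.
    """
    d_mean = 2.0 * float(np.mean(a.radii))
    z = a.positions[:, 2]
    z_top = float(np.quantile(z, coverage))
    z_lo = margin_diameters * d_mean
    z_hi = z_top - margin_diameters * d_mean
    if z_hi <= z_lo:
        raise ValueError("sediment too shallow for a bulk slab")
    return z_lo, z_hi


def select_bulk(a: SphereAssembly, margin_diameters: float = 1.5) -> np.ndarray:
    """Indices of particles in the bulk slab of a sediment."""
    z_lo, z_hi = bulk_slab(a, margin_diameters)
    z = a.positions[:, 2]
    return np.flatnonzero((z >= z_lo) & (z <= z_hi))
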