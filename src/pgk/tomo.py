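"""Synthetic tomogram emulation and sphere extraction.

The emulator turns a ground-truth sphere assembly into a voxel volume the
way a FIB-SEM slice-and-view reconstruction would see it: voxelisation at a
finite pitch (15 nm by default), isotropic sample shrinkage (the
electron-dose shrinkage of resin/Pt-filled samples, ~10–20% linear),
smooth random per-particle surface deformation (beam damage +
reconstruction artifacts), and voxel noise.  The extractor runs the classical distance
transform + marker-controlled watershed chain and returns centroids and
equivalent-volume radii, so the full tomogram -> contact/BOO statistics
chain can be exercised end to end without microscope data.  The two
corrective operations — global isotropic rescale (e.g. x1.2) and
replacement of extracted particles by ideal spheres of one diameter —
mirror the corrections applied to real shrunken tomograms.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
from scipy import ndimage as ndi
from skimage.feature import peak_local_max
from skimage.segmentation import watershed

from pgk.assembly import SphereAssembly, VoxelVolume

__all__ = ["DegradationSpec", "voxelize", "degrade", "extract_spheres",
           "rescale_assembly", "regularize_spheres", "as_walled_sample"]


def as_walled_sample(a: SphereAssembly, pad: Optional[float] = None
                     ) -> SphereAssembly:
    """Re-frame an assembly as a finite walled sample for voxelisation.

    Positions are wrapped into the box, the box is padded by ``pad`` nm
    (default: max radius + 20) on every side, and all axes become walled —
    the geometry a finite tomogram field of view actually has.  Contacts
    that crossed periodic boundaries are severed, so apply this
    consistently to truth and recovery when comparing statistics.
    """
    out = a.wrapped()
    if pad is None:
        pad = float(out.radii.max()) + 20.0
    out.positions = out.positions + pad
    out.box = out.box + 2.0 * pad
    out.periodic = np.array([False] * 3)
    return out


@dataclass
class DegradationSpec:
    """Emulated acquisition damage.

    shrink_factor : linear sample contraction in (0, 1]; 0.8–0.9 emulates
        the 10–20% electron-dose shrinkage
    deform_amplitude : nm; sd of the smooth random surface displacement
    deform_scale : nm; correlation length of the deformation field
    noise_rate : probability of flipping a voxel
    seed : RNG seed (bit-identical output for equal seeds)
    """

    shrink_factor: float = 1.0
    deform_amplitude: float = 0.0
    deform_scale: float = 50.0
    noise_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.shrink_factor <= 1:
            raise ValueError("shrink_factor must be in (0, 1]")
        if not 0 <= self.noise_rate <= 0.2:
            raise ValueError("noise_rate must be in [0, 0.2]")
        if self.deform_amplitude < 0:
            raise ValueError("deform_amplitude must be >= 0")


def voxelize(a: SphereAssembly, pitch: float,
             max_voxels: int = 300_000_000) -> VoxelVolume:
    """Voxelise an assembly: voxel occupied iff its centre is inside a sphere.

    The grid covers the assembly box; spheres wrap on periodic axes.  The
    output grid is labelled (particle index + 1, ties resolved to the
    nearest surface).  Occupied fraction converges to the analytic packing
    fraction as pitch -> 0.
    """
    if pitch <= 0:
        raise ValueError("pitch must be positive")
    shape = tuple(int(np.ceil(b / pitch)) for b in a.box)
    if int(np.prod(shape)) > max_voxels:
        raise MemoryError(
            f"grid {shape} exceeds the {max_voxels}-voxel budget; "
            "use a larger pitch")
    label = np.zeros(shape, dtype=np.int32)
    best = np.full(shape, np.inf, dtype=np.float32)
    pos = a.wrapped().positions
    for i in range(a.n):
        r = a.radii[i]
        for centre in _images(pos[i], r, a):
            lo_idx = np.floor((centre - r) / pitch - 0.5).astype(int)
            hi_idx = np.ceil((centre + r) / pitch + 0.5).astype(int)
            lo_idx = np.maximum(lo_idx, 0)
            hi_idx = np.minimum(hi_idx, shape)
            if np.any(lo_idx >= hi_idx):
                continue
            axes = [(np.arange(lo_idx[ax], hi_idx[ax]) + 0.5) * pitch
                    - centre[ax] for ax in range(3)]
            d2 = (axes[0][:, None, None] ** 2 + axes[1][None, :, None] ** 2
                  + axes[2][None, None, :] ** 2)
            sl = tuple(slice(lo_idx[ax], hi_idx[ax]) for ax in range(3))
            signed = np.sqrt(d2) - r
            inside = signed < 0
            upd = inside & (signed < best[sl])
            best[sl] = np.where(upd, signed, best[sl])
            label[sl] = np.where(upd, i + 1, label[sl])
    return VoxelVolume(label.astype(np.int64), pitch, np.zeros(3))


def _images(centre, r, a: SphereAssembly):
    """The sphere centre plus periodic images that intersect the box."""
    shifts = [[0.0]] * 3
    out = []
    for ax in range(3):
        s = [0.0]
        if a.periodic[ax]:
            if centre[ax] - r < 0:
                s.append(a.box[ax])
            if centre[ax] + r > a.box[ax]:
                s.append(-a.box[ax])
        shifts[ax] = s
    for sx in shifts[0]:
        for sy in shifts[1]:
            for sz in shifts[2]:
                out.append(np.asarray(centre) + np.array([sx, sy, sz]))
    return out


def degrade(vol: VoxelVolume, spec: DegradationSpec) -> VoxelVolume:
    """Apply sample shrinkage, surface deformation and voxel noise.

    Shrinkage contracts the whole sample isotropically by ``shrink_factor``
    (centres and radii alike), emulating the global electron-dose volume
    loss that the later 1/shrink voxel rescale corrects; a binary input is
    connected-component labelled first so labels survive.  Deformation
    adds a smooth Gaussian random field to the signed distance map before
    re-thresholding (the per-particle, non-correctable damage); noise
    flips random voxels.  Deterministic given the seed.
    """
    rng = np.random.default_rng(spec.seed)
    grid = vol.grid
    labelled = grid.copy()
    if labelled.max() <= 1:
        labelled, _ = ndi.label(grid > 0)

    if spec.shrink_factor < 1.0:
        # global isotropic contraction of the sample (nearest-neighbour
        # zoom keeps labels intact); the grid keeps its size and pitch, the
        # content occupies a smaller corner region — exactly what the
        # 1/shrink voxel-volume rescale correction undoes
        s = spec.shrink_factor
        small = ndi.zoom(labelled, zoom=s, order=0, grid_mode=True,
                         mode="grid-constant")
        out = np.zeros_like(labelled)
        sl = tuple(slice(0, min(a, b)) for a, b in zip(small.shape,
                                                       labelled.shape))
        out[sl] = small[sl]
        labelled = out
    mask = labelled > 0

    if spec.deform_amplitude > 0:
        inside = ndi.distance_transform_edt(mask)
        outside = ndi.distance_transform_edt(~mask)
        signed = outside - inside          # negative inside, voxels
        field = rng.standard_normal(mask.shape)
        sigma_vox = max(spec.deform_scale / vol.voxel_pitch, 0.5)
        field = ndi.gaussian_filter(field, sigma_vox)
        sd = field.std()
        if sd > 0:
            field /= sd
        amp_vox = spec.deform_amplitude / vol.voxel_pitch
        mask = (signed + amp_vox * field) < 0

    if spec.noise_rate > 0:
        flips = rng.random(mask.shape) < spec.noise_rate
        mask = mask ^ flips

    # carry labels: each occupied voxel inherits the original label of the
    # nearest originally-occupied voxel
    if labelled.max() > 1:
        idx = ndi.distance_transform_edt(labelled == 0, return_indices=True,
                                         return_distances=False)
        nearest = labelled[tuple(idx)]
        out = np.where(mask, nearest, 0)
    else:
        out = mask.astype(np.int64)
    return VoxelVolume(out.astype(np.int64), vol.voxel_pitch, vol.origin.copy())


def extract_spheres(vol: VoxelVolume,
                    expected_radius: Optional[float] = None,
                    marker_smooth_frac: float = 0.15,
                    min_marker_sep_frac: float = 0.6
                    ) -> Optional[SphereAssembly]:
    """Segment a volume into spheres: EDT -> smoothed maxima -> watershed.

    Markers are local maxima of the Gaussian-smoothed Euclidean distance
    transform (smoothing sd = ``marker_smooth_frac`` x expected radius;
    minimum marker separation = ``min_marker_sep_frac`` x expected
    diameter).  Returns centroids and equivalent-volume radii
    r = (3V / 4 pi)^{1/3}; labels are carried.  ``None`` for an empty
    volume (no particles is not an error).
    """
    mask = vol.grid > 0
    if not np.any(mask):
        return None
    pitch = vol.voxel_pitch
    edt = ndi.distance_transform_edt(mask).astype(float)
    if expected_radius is None:
        expected_radius = float(edt.max()) * pitch * 0.9
    r_vox = max(expected_radius / pitch, 1.0)
    smoothed = ndi.gaussian_filter(edt, sigma=max(marker_smooth_frac * r_vox, 0.5))
    # candidate maxima with a small footprint, then greedy Euclidean
    # suppression at min_marker_sep_frac x expected diameter (plateaus and
    # twin maxima inside one particle collapse onto the strongest)
    cand = peak_local_max(smoothed, min_distance=2,
                          threshold_abs=0.3 * r_vox, exclude_border=False)
    if len(cand) == 0:
        cand = np.array([np.unravel_index(np.argmax(smoothed), smoothed.shape)])
    order = np.argsort(-smoothed[tuple(cand.T)])
    cand = cand[order].astype(float)
    min_sep = min_marker_sep_frac * 2.0 * r_vox
    peaks: list = []
    for p in cand:
        if all(np.linalg.norm(p - q) >= min_sep for q in peaks):
            peaks.append(p)
    peaks = np.asarray(peaks, dtype=int)
    markers = np.zeros(mask.shape, dtype=np.int32)
    for k, p in enumerate(peaks, start=1):
        markers[tuple(p)] = k
    labels = watershed(-edt, markers=markers, mask=mask)

    ids = np.arange(1, labels.max() + 1)
    counts = ndi.sum_labels(mask, labels, ids)
    keep = counts > 0
    ids = ids[keep]
    counts = counts[keep]
    centroids = np.asarray(ndi.center_of_mass(mask, labels, ids))
    pos = (centroids + 0.5) * pitch + vol.origin
    radii = (3.0 * counts * pitch ** 3 / (4.0 * np.pi)) ** (1.0 / 3.0)
    box = np.array(vol.grid.shape) * pitch
    pos = np.clip(pos, 1e-9, box - 1e-9)
    return SphereAssembly(pos, radii, box, np.array([False] * 3),
                          labels=ids.astype(int),
                          meta={"source": "extract_spheres",
                                "pitch_nm": pitch,
                                "marker_smooth_frac": marker_smooth_frac,
                                "min_marker_sep_frac": min_marker_sep_frac})


def rescale_assembly(a: SphereAssembly, factor: float) -> SphereAssembly:
    """Isotropically rescale positions, radii and box by ``factor``.

    The packing fraction is invariant; contact statistics at zero gap are
    invariant (at a fixed physical gap the gap must be scaled alongside).
    """
    if factor <= 0:
        raise ValueError("factor must be positive")
    out = a.copy()
    out.positions = out.positions * factor
    out.radii = out.radii * factor
    out.box = out.box * factor
    out.meta["rescale_factor"] = factor * a.meta.get("rescale_factor", 1.0)
    return out


def regularize_spheres(a: SphereAssembly, target_diameter: float
                       ) -> SphereAssembly:
    """Replace every particle by an ideal sphere of ``target_diameter``.

    Centres are preserved.  The overlap report (pair count and maximum
    overlap depth, nm) produced by the uniform radii goes to ``meta``.
    """
    if target_diameter <= 0:
        raise ValueError("target_diameter must be positive")
    out = a.copy()
    out.radii = np.full(a.n, target_diameter / 2.0)
    from pgk.contacts import contact_graph
    g = contact_graph(out, gap_tol=0.0)
    n_overlap = 0
    max_depth = 0.0
    if len(g.edges):
        pos = out.wrapped().positions
        dr = out.minimum_image(pos[g.edges[:, 0]] - pos[g.edges[:, 1]])
        d = np.linalg.norm(dr, axis=1)
        depth = target_diameter - d
        ov = depth > 1e-9
        n_overlap = int(np.sum(ov))
        max_depth = float(depth[ov].max()) if n_overlap else 0.0
    out.meta.update({"overlap_pairs": n_overlap,
                     "max_overlap_depth_nm": max_depth,
                     "regularized_diameter_nm": target_diameter})
    return out
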