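"""Core data model and file I/O.

Four containers circulate through every stage of the pipeline:

``SphereAssembly``
    particle centres, radii, optional orientations and labels, in a
    rectangular box whose axes are individually periodic or walled.
``VoxelVolume``
    a 3D occupancy/label grid with a physical voxel pitch — the stand-in for
    a FIB-SEM tomogram.
``ScatteringProfile``
    a 1D small-angle scattering curve (q, I, optional sigma).
``RunConfig``
    seed + stage parameters for reproducible pipeline runs.

Coordinate convention: Cartesian nanometres with the origin at the box
corner.  Voxel index (i, j, k) maps to the physical point
``origin + (i + 0.5, j + 0.5, k + 0.5) * pitch``.

File formats are deliberately plain text / standard containers: extended XYZ
for assemblies (radius as a fourth column, box metadata in the comment
line), TIFF stacks or NRRD for volumes, 2–3 column whitespace/CSV text for
profiles, YAML for configs.
"""

from __future__ import annotations

import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import tifffile
import yaml

__all__ = [
    "SphereAssembly", "VoxelVolume", "ScatteringProfile", "RunConfig",
    "read_assembly", "write_assembly", "read_volume", "write_volume",
    "read_profile", "write_profile", "load_config",
]


class ParseError(ValueError):
    """Malformed input file; message carries the file and line number."""


# ---------------------------------------------------------------------------
# SphereAssembly
# ---------------------------------------------------------------------------

@dataclass
class SphereAssembly:
    """A collection of spheres in a rectangular, optionally periodic box.

    Parameters
    ----------
    positions : (N, 3) float array, nm
    radii : (N,) float array, nm, all > 0
    box : (3,) float array, nm — edge lengths; the box spans [0, L) per axis
    periodic : (3,) bool array — True: periodic axis, False: walled axis
    orientations : optional (N, 4) unit quaternions (w, x, y, z)
    labels : optional (N,) integer ids
    meta : free-form metadata dictionary (seed, provenance, ...)
    """

    positions: np.ndarray
    radii: np.ndarray
    box: np.ndarray
    periodic: np.ndarray
    orientations: Optional[np.ndarray] = None
    labels: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.positions = np.atleast_2d(np.asarray(self.positions, dtype=float))
        self.radii = np.asarray(self.radii, dtype=float).ravel()
        self.box = np.asarray(self.box, dtype=float).ravel()
        self.periodic = np.asarray(self.periodic, dtype=bool).ravel()
        if self.positions.shape != (len(self.radii), 3):
            raise ValueError(
                f"positions shape {self.positions.shape} inconsistent with "
                f"{len(self.radii)} radii")
        if len(self.radii) < 1:
            raise ValueError("assembly must contain at least one particle")
        if self.box.shape != (3,) or np.any(self.box <= 0):
            raise ValueError("box must be three positive edge lengths")
        if self.periodic.shape != (3,):
            raise ValueError("periodic must be three boolean flags")
        if np.any(self.radii <= 0):
            bad = int(np.argmax(self.radii <= 0))
            raise ValueError(f"radius of particle {bad} is not positive")
        for ax in range(3):
            x = self.positions[:, ax]
            if not self.periodic[ax] and (np.any(x < -1e-9) or
                                          np.any(x > self.box[ax] + 1e-9)):
                raise ValueError(f"particles outside walled axis {ax}")
        if self.orientations is not None:
            self.orientations = np.asarray(self.orientations, dtype=float)
            if self.orientations.shape != (self.n, 4):
                raise ValueError("orientations must be (N, 4) quaternions")
            norms = np.linalg.norm(self.orientations, axis=1)
            if np.any(np.abs(norms - 1.0) > 1e-9):
                raise ValueError("orientations must be unit quaternions (|q| = 1 within 1e-9)")
        if self.labels is not None:
            self.labels = np.asarray(self.labels, dtype=int).ravel()
            if self.labels.shape != (self.n,):
                raise ValueError("labels must be one integer per particle")

    @property
    def n(self) -> int:
        return len(self.radii)

    def copy(self) -> "SphereAssembly":
        return SphereAssembly(
            self.positions.copy(), self.radii.copy(), self.box.copy(),
            self.periodic.copy(),
            None if self.orientations is None else self.orientations.copy(),
            None if self.labels is None else self.labels.copy(),
            dict(self.meta))

    def wrapped(self) -> "SphereAssembly":
        """Return a copy with positions wrapped into [0, L) on periodic axes."""
        out = self.copy()
        for ax in range(3):
            if self.periodic[ax]:
                out.positions[:, ax] %= self.box[ax]
        return out

    def minimum_image(self, dr: np.ndarray) -> np.ndarray:
        """Apply the minimum-image convention to displacement vectors."""
        dr = np.array(dr, dtype=float, copy=True)
        for ax in range(3):
            if self.periodic[ax]:
                L = self.box[ax]
                dr[..., ax] -= L * np.round(dr[..., ax] / L)
        return dr

    @property
    def volume(self) -> float:
        return float(np.prod(self.box))

    def sphere_volume(self) -> float:
        """Total material volume, ignoring any sphere overlaps."""
        return float(np.sum(4.0 / 3.0 * np.pi * self.radii ** 3))


# ---------------------------------------------------------------------------
# VoxelVolume
# ---------------------------------------------------------------------------

@dataclass
class VoxelVolume:
    """A 3D occupancy (0/1) or label (non-negative int) grid.

    ``grid[i, j, k]`` covers the cube whose centre sits at
    ``origin + (i+0.5, j+0.5, k+0.5) * voxel_pitch``.
    """

    grid: np.ndarray
    voxel_pitch: float
    origin: np.ndarray = field(default_factory=lambda: np.zeros(3))

    def __post_init__(self) -> None:
        self.grid = np.asarray(self.grid)
        if self.grid.ndim != 3 or min(self.grid.shape) < 1:
            raise ValueError("grid must be a non-empty 3D array")
        if not np.issubdtype(self.grid.dtype, np.integer):
            if np.any(self.grid != self.grid.astype(np.int64)):
                raise ValueError("grid must hold integer occupancy/labels")
            self.grid = self.grid.astype(np.int64)
        if np.any(self.grid < 0):
            raise ValueError("labels must be non-negative")
        self.voxel_pitch = float(self.voxel_pitch)
        if self.voxel_pitch <= 0:
            raise ValueError("voxel_pitch must be positive")
        self.origin = np.asarray(self.origin, dtype=float).ravel()
        if self.origin.shape != (3,):
            raise ValueError("origin must be a 3-vector")

    @property
    def shape(self) -> tuple:
        return self.grid.shape

    def occupancy_fraction(self) -> float:
        return float(np.count_nonzero(self.grid)) / self.grid.size

    def voxel_centres_axes(self):
        """Per-axis physical coordinates of voxel centres."""
        return tuple(self.origin[a] + (np.arange(self.grid.shape[a]) + 0.5) * self.voxel_pitch
                     for a in range(3))


# ---------------------------------------------------------------------------
# ScatteringProfile
# ---------------------------------------------------------------------------

@dataclass
class ScatteringProfile:
    """A 1D scattering curve: q (nm^-1, strictly increasing), I(q) >= 0."""

    q: np.ndarray
    intensity: np.ndarray
    sigma: Optional[np.ndarray] = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.q = np.asarray(self.q, dtype=float).ravel()
        self.intensity = np.asarray(self.intensity, dtype=float).ravel()
        if self.q.shape != self.intensity.shape:
            raise ValueError("q and intensity must have equal length")
        if len(self.q) < 2:
            raise ValueError("profile needs at least two points")
        if np.any(np.diff(self.q) <= 0):
            raise ValueError("q must be strictly increasing")
        if np.any(self.intensity < 0):
            raise ValueError("intensity must be non-negative")
        if self.sigma is not None:
            self.sigma = np.asarray(self.sigma, dtype=float).ravel()
            if self.sigma.shape != self.q.shape:
                raise ValueError("sigma length must match q")
            if np.any(self.sigma <= 0):
                raise ValueError("sigma must be strictly positive")


# ---------------------------------------------------------------------------
# RunConfig
# ---------------------------------------------------------------------------

@dataclass
class RunConfig:
    """Seed + stage parameters for a pipeline run.

    All randomness in the package flows from ``seed`` through
    ``numpy.random.SeedSequence``; every stage report echoes the seed.
    """

    seed: int
    scenario: str = ""
    voxel_pitch: float = 15.0
    contact_gap: float = 15.0
    outdir: Optional[str] = None
    stages: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.seed = int(self.seed)
        if self.contact_gap < 0:
            raise ValueError("contact_gap must be >= 0")
        if self.voxel_pitch <= 0:
            raise ValueError("voxel_pitch must be > 0")

    def spawn(self, n: int) -> list:
        """Derive n independent child generators from the master seed."""
        return [np.random.default_rng(s)
                for s in np.random.SeedSequence(self.seed).spawn(n)]


def load_config(path) -> RunConfig:
    """Load a YAML run configuration.

    Recognised top-level keys: ``seed`` (required), ``scenario``,
    ``voxel_pitch``, ``contact_gap``, ``outdir``; everything else is kept
    verbatim in ``stages``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    if not isinstance(raw, dict) or "seed" not in raw:
        raise ParseError(f"{path}: config must be a mapping with a 'seed' key")
    known = {k: raw.pop(k) for k in
             ("seed", "scenario", "voxel_pitch", "contact_gap", "outdir")
             if k in raw}
    return RunConfig(stages=raw, **known)


# ---------------------------------------------------------------------------
# Extended XYZ reader / writer
# ---------------------------------------------------------------------------

_KV_RE = re.compile(r'(\w+)=(?:"([^"]*)"|(\S+))')


def write_assembly(a: SphereAssembly, path, precision: int = 9) -> None:
    """Write an assembly as extended XYZ.

    Line 1: N.  Line 2: key=value metadata — ``box="Lx Ly Lz"``,
    ``boundary="pp w ..."`` (p periodic / w walled per axis), ``columns``.
    Then one whitespace row per particle: x y z radius [label] [qw qx qy qz].
    """
    cols = ["x", "y", "z", "radius"]
    if a.labels is not None:
        cols.append("label")
    if a.orientations is not None:
        cols += ["qw", "qx", "qy", "qz"]
    bflags = " ".join("p" if p else "w" for p in a.periodic)
    box = " ".join(f"{v:.{precision}g}" for v in a.box)
    header = f'box="{box}" boundary="{bflags}" columns="{" ".join(cols)}"'
    if "seed" in a.meta:
        header += f' seed={a.meta["seed"]}'
    lines = [str(a.n), header]
    fmt = f"{{:.{precision}g}}"
    for i in range(a.n):
        parts = [fmt.format(v) for v in a.positions[i]] + [fmt.format(a.radii[i])]
        if a.labels is not None:
            parts.append(str(int(a.labels[i])))
        if a.orientations is not None:
            parts += [fmt.format(v) for v in a.orientations[i]]
        lines.append(" ".join(parts))
    Path(path).write_text("\n".join(lines) + "\n")


def read_assembly(path) -> SphereAssembly:
    """Read an extended-XYZ assembly written by :func:`write_assembly`.

    Raises :class:`ParseError` naming the offending line for malformed
    records; a missing box header is an explicit error, never defaulted.
    """
    text = Path(path).read_text()
    lines = text.splitlines()
    if len(lines) < 2:
        raise ParseError(f"{path}: file too short for an extended-XYZ header")
    try:
        n = int(lines[0].strip())
    except ValueError:
        raise ParseError(f"{path}:1: first line must be the particle count") from None
    kv = {m.group(1): (m.group(2) if m.group(2) is not None else m.group(3))
          for m in _KV_RE.finditer(lines[1])}
    if "box" not in kv:
        raise ParseError(f"{path}:2: missing box=\"Lx Ly Lz\" header")
    box = np.array([float(v) for v in kv["box"].split()])
    if "boundary" not in kv:
        raise ParseError(f"{path}:2: missing boundary=\"...\" header")
    bnd = kv["boundary"].split()
    if len(bnd) != 3 or any(b not in ("p", "w") for b in bnd):
        raise ParseError(f"{path}:2: boundary flags must be three of p|w")
    periodic = np.array([b == "p" for b in bnd])
    cols = kv.get("columns", "x y z radius").split()
    if cols[:4] != ["x", "y", "z", "radius"]:
        raise ParseError(f"{path}:2: first four columns must be x y z radius")
    has_label = "label" in cols
    has_quat = "qw" in cols
    if len(lines) < 2 + n:
        raise ParseError(f"{path}: expected {n} particle records, found {len(lines) - 2}")

    pos = np.empty((n, 3))
    rad = np.empty(n)
    lab = np.empty(n, dtype=int) if has_label else None
    quat = np.empty((n, 4)) if has_quat else None
    ncol = len(cols)
    for i in range(n):
        lineno = 3 + i
        parts = lines[2 + i].split()
        if len(parts) != ncol:
            raise ParseError(f"{path}:{lineno}: expected {ncol} fields, got {len(parts)}")
        try:
            vals = [float(v) for v in parts]
        except ValueError:
            raise ParseError(f"{path}:{lineno}: non-numeric field") from None
        pos[i] = vals[:3]
        rad[i] = vals[3]
        if rad[i] <= 0:
            raise ParseError(f"{path}:{lineno}: non-positive radius {rad[i]}")
        k = 4
        if has_label:
            lab[i] = int(vals[k]); k += 1
        if has_quat:
            quat[i] = vals[k:k + 4]
    meta = {}
    if "seed" in kv:
        meta["seed"] = int(kv["seed"])
    try:
        return SphereAssembly(pos, rad, box, periodic, quat, lab, meta)
    except ValueError as exc:
        raise ParseError(f"{path}: {exc}") from None


# ---------------------------------------------------------------------------
# Volume reader / writer (TIFF stack, NRRD)
# ---------------------------------------------------------------------------

def _detect_volume_format(path, fmt: Optional[str]) -> str:
    if fmt is not None:
        return fmt
    s = str(path).lower()
    if s.endswith((".tif", ".tiff")):
        return "tiff-stack"
    if s.endswith(".nrrd"):
        return "nrrd"
    raise ValueError(f"cannot infer volume format from {path!r}; pass format=")


def write_volume(vol: VoxelVolume, path, format: Optional[str] = None) -> None:
    """Write a volume as a multi-page TIFF or a (text-header) NRRD file.

    The voxel pitch and origin travel in the TIFF image description (JSON)
    or in NRRD ``spacings`` / ``axis mins`` fields.
    """
    fmt = _detect_volume_format(path, format)
    if fmt == "tiff-stack":
        desc = json.dumps({"voxel_pitch_nm": vol.voxel_pitch,
                           "origin_nm": list(vol.origin)})
        grid = vol.grid
        dtype = np.uint8 if grid.max(initial=0) < 256 else np.uint32
        tifffile.imwrite(path, grid.astype(dtype), description=desc)
    elif fmt == "nrrd":
        grid = vol.grid
        dtype = "uint8" if grid.max(initial=0) < 256 else "uint32"
        sp = vol.voxel_pitch
        header = (
            "NRRD0004\n"
            "# pgk voxel volume\n"
            "type: {t}\n"
            "dimension: 3\n"
            "sizes: {s0} {s1} {s2}\n"
            "encoding: raw\n"
            "endian: little\n"
            "spacings: {sp} {sp} {sp}\n"
            "axis mins: {o0} {o1} {o2}\n"
            "\n"
        ).format(t=dtype, s0=grid.shape[0], s1=grid.shape[1], s2=grid.shape[2],
                 sp=repr(float(sp)), o0=repr(float(vol.origin[0])),
                 o1=repr(float(vol.origin[1])), o2=repr(float(vol.origin[2])))
        # NRRD stores the fastest axis first; C-order numpy is slowest-first.
        payload = np.ascontiguousarray(grid.astype(dtype)).tobytes()
        with open(path, "wb") as fh:
            fh.write(header.encode())
            fh.write(payload)
    else:
        raise ValueError(f"unsupported volume format {fmt!r}")


def read_volume(path, format: Optional[str] = None) -> VoxelVolume:
    fmt = _detect_volume_format(path, format)
    if fmt == "tiff-stack":
        with tifffile.TiffFile(path) as tf:
            grid = tf.asarray()
            desc = tf.pages[0].description or "{}"
        try:
            meta = json.loads(desc)
        except json.JSONDecodeError:
            meta = {}
        pitch = float(meta.get("voxel_pitch_nm", 1.0))
        origin = np.asarray(meta.get("origin_nm", [0, 0, 0]), dtype=float)
        return VoxelVolume(grid.astype(np.int64), pitch, origin)
    if fmt == "nrrd":
        with open(path, "rb") as fh:
            raw = fh.read()
        head, _, payload = raw.partition(b"\n\n")
        fields = {}
        for ln in head.decode().splitlines()[1:]:
            if ":" in ln and not ln.startswith("#"):
                k, _, v = ln.partition(":")
                fields[k.strip()] = v.strip()
        sizes = [int(v) for v in fields["sizes"].split()]
        dtype = np.uint8 if fields["type"] == "uint8" else np.uint32
        grid = np.frombuffer(payload, dtype=dtype)[: int(np.prod(sizes))]
        grid = grid.reshape(sizes).astype(np.int64)
        pitch = float(fields["spacings"].split()[0])
        origin = np.array([float(v) for v in fields.get("axis mins", "0 0 0").split()])
        return VoxelVolume(grid, pitch, origin)
    raise ValueError(f"unsupported volume format {fmt!r}")


# ---------------------------------------------------------------------------
# Scattering profile reader / writer
# ---------------------------------------------------------------------------

def write_profile(p: ScatteringProfile, path) -> None:
    cols = [p.q, p.intensity] + ([p.sigma] if p.sigma is not None else [])
    header = "q_nm^-1 intensity" + (" sigma" if p.sigma is not None else "")
    np.savetxt(path, np.column_stack(cols), header=header)


def read_profile(path) -> ScatteringProfile:
    """Read a 2–3 column whitespace or comma-separated (q, I[, sigma]) file."""
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            s = line.strip()
            if not s or s.startswith(("#", "%")):
                continue
            parts = re.split(r"[,\s]+", s)
            try:
                vals = [float(v) for v in parts]
            except ValueError:
                raise ParseError(f"{path}:{lineno}: non-numeric field") from None
            if len(vals) not in (2, 3):
                raise ParseError(f"{path}:{lineno}: expected 2 or 3 columns")
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    ncol = len(rows[0])
    if any(len(r) != ncol for r in rows):
        raise ParseError(f"{path}: inconsistent column count")
    arr = np.asarray(rows)
    sigma = arr[:, 2] if ncol == 3 else None
    return ScatteringProfile(arr[:, 0], arr[:, 1], sigma)
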