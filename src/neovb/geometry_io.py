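"""Meshes, multi-channel volumes, per-vertex maps and cohort tables.

Coordinate conventions used throughout the package:

* voxel indices are 0-based triples ``(i, j, k)``;
* the affine maps a voxel *index* (not a voxel corner) to world mm, so the
  centre of voxel ``(i, j, k)`` sits at ``affine @ (i, j, k, 1)``;
* world coordinates are millimetres and are shared between a subject's
  surface mesh and feature volume.

Surfaces are read/written as GIFTI (``.surf.gii``), per-vertex maps as GIFTI
functional files (``.func.gii`` / ``.shape.gii``), volumes as NIfTI-1
(``.nii`` / ``.nii.gz``).  A plain-text sidecar format (``.mesh.txt`` for
meshes, ``.map.txt`` for vertex maps) is supported so unit-test fixtures need
no binary files.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import nibabel as nib
import numpy as np
import pandas as pd

#: fixed channel order of every feature volume
CHANNEL_NAMES = ("FA", "MD", "AD", "RD", "NDI_mod", "ODI_mod")


class MeshError(ValueError):
    """Raised for malformed or inconsistent surface meshes."""


@dataclass(frozen=True)
class SurfaceMesh:
    """Triangulated hemisphere geometry in world millimetres."""

    vertex_coords: np.ndarray  # (V, 3) float
    triangles: np.ndarray      # (T, 3) int, 0-based

    def __post_init__(self):
        coords = np.asarray(self.vertex_coords, dtype=float)
        tris = np.asarray(self.triangles, dtype=np.int64)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise MeshError("vertex_coords must be (V, 3)")
        if tris.ndim != 2 or tris.shape[1] != 3:
            raise MeshError("triangles must be (T, 3)")
        if coords.shape[0] < 4:
            raise MeshError("mesh must have at least 4 vertices")
        if tris.min(initial=0) < 0 or tris.max(initial=-1) >= coords.shape[0]:
            raise MeshError(
                f"triangle index out of range [0, {coords.shape[0]})"
            )
        used = np.zeros(coords.shape[0], dtype=bool)
        used[tris.ravel()] = True
        if not used.all():
            orphans = np.flatnonzero(~used)
            raise MeshError(f"orphan vertices not in any triangle: {orphans[:10].tolist()}")
        object.__setattr__(self, "vertex_coords", coords)
        object.__setattr__(self, "triangles", tris)

    @property
    def vertex_count(self) -> int:
        return self.vertex_coords.shape[0]

    @property
    def adjacency(self) -> list[np.ndarray]:
        """One-ring neighbour lists (symmetric, no self loops), cached."""
        cached = getattr(self, "_adjacency", None)
        if cached is None:
            nbr: list[set[int]] = [set() for _ in range(self.vertex_count)]
            for a, b, c in self.triangles:
                nbr[a].update((b, c))
                nbr[b].update((a, c))
                nbr[c].update((a, b))
            cached = [np.array(sorted(s), dtype=np.int64) for s in nbr]
            object.__setattr__(self, "_adjacency", cached)
        return cached

    def edges(self) -> np.ndarray:
        """Unique undirected edges as an (E, 2) array with e[:,0] < e[:,1]."""
        t = self.triangles
        e = np.concatenate([t[:, [0, 1]], t[:, [1, 2]], t[:, [0, 2]]])
        e = np.sort(e, axis=1)
        return np.unique(e, axis=0)

    def edge_lengths(self) -> np.ndarray:
        e = self.edges()
        d = self.vertex_coords[e[:, 0]] - self.vertex_coords[e[:, 1]]
        return np.linalg.norm(d, axis=1)

    def vertex_areas(self) -> np.ndarray:
        """Barycentric vertex areas: one third of each incident triangle."""
        p = self.vertex_coords[self.triangles]
        tri_area = 0.5 * np.linalg.norm(
            np.cross(p[:, 1] - p[:, 0], p[:, 2] - p[:, 0]), axis=1
        )
        areas = np.zeros(self.vertex_count)
        for col in range(3):
            np.add.at(areas, self.triangles[:, col], tri_area / 3.0)
        return areas


@dataclass
class FeatureVolume:
    """Multi-channel 3D grid of microstructural metrics.

    ``data`` has shape (X, Y, Z, C) with the channel order fixed to
    :data:`CHANNEL_NAMES`; ``mask`` marks brain-tissue voxels.
    """

    data: np.ndarray          # (X, Y, Z, C)
    affine: np.ndarray        # (4, 4)
    mask: np.ndarray          # (X, Y, Z) bool

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        self.affine = np.asarray(self.affine, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.data.ndim != 4:
            raise ValueError("data must be 4D (X, Y, Z, C)")
        if self.mask.shape != self.data.shape[:3]:
            raise ValueError("mask shape does not match data grid")
        if abs(np.linalg.det(self.affine[:3, :3])) < 1e-12:
            raise ValueError("affine is singular")
        if not self.mask.any():
            raise ValueError("empty mask")
        if not np.isfinite(self.data[self.mask]).all():
            raise ValueError("non-finite values inside the mask")

    @property
    def shape(self) -> tuple[int, ...]:
        return self.data.shape

    @property
    def n_channels(self) -> int:
        return self.data.shape[3]

    @property
    def voxel_size(self) -> np.ndarray:
        """mm per axis: column norms of the linear part of the affine."""
        return np.linalg.norm(self.affine[:3, :3], axis=0)


@dataclass
class SubjectRecord:
    subject_id: str
    group: str                # "preterm" | "term"
    pma_at_scan: float        # weeks
    sex: str                  # "M" | "F"
    mesh: SurfaceMesh
    features: FeatureVolume
    nuisance_map: np.ndarray | None = None  # per-vertex scalar, optional

    def __post_init__(self):
        if self.pma_at_scan <= 0:
            raise ValueError("pma_at_scan must be positive")
        if self.group not in ("preterm", "term"):
            raise ValueError(f"unknown group {self.group!r}")
        if self.sex not in ("M", "F"):
            raise ValueError(f"unknown sex {self.sex!r}")
        if self.nuisance_map is not None:
            self.nuisance_map = np.asarray(self.nuisance_map, dtype=float)
            if self.nuisance_map.shape != (self.mesh.vertex_count,):
                raise ValueError("nuisance_map length does not match mesh")


@dataclass
class CohortTable:
    """All subjects of one hemisphere analysis."""

    subjects: list[SubjectRecord]
    hemisphere: str = "L"
    effect_vertices: np.ndarray | None = None  # ground truth when simulated
    paths: dict = field(default_factory=dict)

    def __post_init__(self):
        ids = [s.subject_id for s in self.subjects]
        if len(set(ids)) != len(ids):
            raise ValueError("duplicate subject_ids in cohort")
        if self.hemisphere not in ("L", "R"):
            raise ValueError("hemisphere must be 'L' or 'R'")

    def __len__(self) -> int:
        return len(self.subjects)

    @property
    def groups(self) -> np.ndarray:
        return np.array([s.group for s in self.subjects])

    def require_both_groups(self):
        g = set(self.groups)
        if not {"preterm", "term"} <= g:
            raise ValueError("cohort must contain both preterm and term subjects")


# ---------------------------------------------------------------------------
# coordinate transforms
# ---------------------------------------------------------------------------

def world_to_voxel(affine: np.ndarray, points_mm: np.ndarray) -> np.ndarray:
    """Map world-mm points to nearest 0-based voxel indices.

    Applies the inverse affine and rounds each coordinate to the nearest
    integer with ties away from zero (0.5 -> 1, -0.5 -> -1).  No bounds
    checking is performed.
    """
    affine = np.asarray(affine, dtype=float)
    if abs(np.linalg.det(affine[:3, :3])) < 1e-12:
        raise ValueError("affine is singular")
    pts = np.atleast_2d(np.asarray(points_mm, dtype=float))
    inv = np.linalg.inv(affine)
    ijk = pts @ inv[:3, :3].T + inv[:3, 3]
    # round half away from zero (np.round would round half to even)
    idx = np.sign(ijk) * np.floor(np.abs(ijk) + 0.5)
    idx = idx.astype(np.int64)
    if np.asarray(points_mm).ndim == 1:
        return idx[0]
    return idx


# ---------------------------------------------------------------------------
# mesh I/O
# ---------------------------------------------------------------------------

def load_mesh(path: str | Path) -> SurfaceMesh:
    """Load a surface mesh from GIFTI (.gii) or plain text (.mesh.txt)."""
    path = Path(path)
    if path.suffix == ".gii":
        img = nib.load(str(path))
        coords = tris = None
        for arr in img.darrays:
            code = arr.intent
            if code == nib.nifti1.intent_codes["NIFTI_INTENT_POINTSET"]:
                coords = np.asarray(arr.data, dtype=float)
            elif code == nib.nifti1.intent_codes["NIFTI_INTENT_TRIANGLE"]:
                tris = np.asarray(arr.data, dtype=np.int64)
        if coords is None or tris is None:
            raise MeshError(f"{path}: missing POINTSET or TRIANGLE data array")
        return SurfaceMesh(coords, tris)
    return _load_mesh_text(path)


def save_mesh(path: str | Path, mesh: SurfaceMesh) -> None:
    path = Path(path)
    if path.suffix == ".gii":
        pts = nib.gifti.GiftiDataArray(
            mesh.vertex_coords.astype(np.float32), intent="NIFTI_INTENT_POINTSET"
        )
        tri = nib.gifti.GiftiDataArray(
            mesh.triangles.astype(np.int32), intent="NIFTI_INTENT_TRIANGLE"
        )
        nib.save(nib.gifti.GiftiImage(darrays=[pts, tri]), str(path))
    else:
        _save_mesh_text(path, mesh)


def _load_mesh_text(path: Path) -> SurfaceMesh:
    """Plain-text mesh: header line 'V T', V coordinate lines, T index lines."""
    lines = [ln for ln in path.read_text().splitlines()
             if ln.strip() and not ln.startswith("#")]
    try:
        nv, nt = (int(x) for x in lines[0].split())
    except (ValueError, IndexError) as exc:
        raise MeshError(f"{path}: bad header line (expected 'V T')") from exc
    if len(lines) != 1 + nv + nt:
        raise MeshError(f"{path}: expected {nv} vertex and {nt} triangle lines")
    try:
        coords = np.array([[float(x) for x in ln.split()] for ln in lines[1:1 + nv]])
        tris = np.array([[int(x) for x in ln.split()] for ln in lines[1 + nv:]],
                        dtype=np.int64)
    except ValueError as exc:
        raise MeshError(f"{path}: unparseable vertex or triangle line") from exc
    return SurfaceMesh(coords, tris)


def _save_mesh_text(path: Path, mesh: SurfaceMesh) -> None:
    with open(path, "w") as fh:
        fh.write(f"{mesh.vertex_count} {len(mesh.triangles)}\n")
        for p in mesh.vertex_coords:
            fh.write(f"{float(p[0])!r} {float(p[1])!r} {float(p[2])!r}\n")
        for t in mesh.triangles:
            fh.write(f"{t[0]} {t[1]} {t[2]}\n")


# ---------------------------------------------------------------------------
# volume I/O
# ---------------------------------------------------------------------------

def load_feature_volume(channel_paths: Sequence[str | Path],
                        mask_path: str | Path) -> FeatureVolume:
    """Stack six single-channel NIfTI volumes (fixed order) plus a mask.

    All inputs must share shape and affine; the affine comparison uses an
    absolute tolerance of 1e-4 mm.
    """
    if len(channel_paths) != len(CHANNEL_NAMES):
        raise ValueError(
            f"expected {len(CHANNEL_NAMES)} channel volumes, got {len(channel_paths)}"
        )
    imgs = [nib.load(str(p)) for p in channel_paths]
    mask_img = nib.load(str(mask_path))
    ref_shape, ref_affine = imgs[0].shape, imgs[0].affine
    bad = [str(p) for p, im in zip(list(channel_paths) + [mask_path],
                                   imgs + [mask_img])
           if im.shape[:3] != ref_shape[:3]
           or not np.allclose(im.affine, ref_affine, atol=1e-4)]
    if bad:
        raise ValueError(f"shape/affine mismatch in inputs: {bad}")
    data = np.stack([np.asarray(im.dataobj, dtype=float) for im in imgs], axis=-1)
    mask = np.asarray(mask_img.dataobj) > 0
    if not mask.any():
        raise ValueError("empty mask")
    return FeatureVolume(data=data, affine=ref_affine, mask=mask)


def save_volume(path: str | Path, data: np.ndarray, affine: np.ndarray) -> None:
    nib.save(nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine), str(path))


# ---------------------------------------------------------------------------
# per-vertex map I/O
# ---------------------------------------------------------------------------

def save_vertex_map(path: str | Path, values: np.ndarray, mesh: SurfaceMesh) -> None:
    """Write a per-vertex scalar map (GIFTI .func.gii/.shape.gii or .map.txt).

    NaN encodes a missing vertex; the round trip preserves finite values
    bit-identically and keeps missingness.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (mesh.vertex_count,):
        raise ValueError(
            f"map length {values.shape} does not match vertex count {mesh.vertex_count}"
        )
    path = Path(path)
    if path.suffix == ".gii":
        # GIFTI functional arrays are float32 by standard; the plain-text
        # format keeps full float64 precision.
        arr = nib.gifti.GiftiDataArray(values.astype(np.float32),
                                       intent="NIFTI_INTENT_NONE")
        nib.save(nib.gifti.GiftiImage(darrays=[arr]), str(path))
    else:
        with open(path, "w") as fh:
            for v in values:
                fh.write("nan\n" if np.isnan(v) else f"{float(v)!r}\n")


def load_vertex_map(path: str | Path) -> np.ndarray:
    path = Path(path)
    if path.suffix == ".gii":
        img = nib.load(str(path))
        return np.asarray(img.darrays[0].data, dtype=np.float64)
    return np.array([float(ln) for ln in path.read_text().split()], dtype=np.float64)


# ---------------------------------------------------------------------------
# cohort table I/O
# ---------------------------------------------------------------------------

COHORT_COLUMNS = ["subject_id", "group", "pma_at_scan", "sex",
                  "mesh_path", "features_path", "mask_path", "nuisance_path"]


def save_cohort_csv(path: str | Path, rows: list[dict]) -> None:
    pd.DataFrame(rows, columns=COHORT_COLUMNS).to_csv(path, index=False)


def load_cohort_csv(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS[:6] if c not in df.columns]
    if missing:
        raise ValueError(f"cohort table missing columns: {missing}")
    if df["subject_id"].duplicated().any():
        raise ValueError("duplicate subject_ids in cohort table")
    return df


def save_json(path: str | Path, obj: dict) -> None:
    with open(path, "w") as fh:
        json.dump(obj, fh, indent=2, default=_json_default)


def _json_default(o):
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
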