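"""Per-vertex Vogt-Bailey (VB) index with a hybrid surface-to-volume searchlight.

At each surface vertex the one-ring (the vertex plus its mesh neighbours) is
mapped to nearest voxels in the subject's native volume; voxels outside the
tissue mask or outside the 3x3x3 voxel cube centred on the vertex's own voxel
are discarded and duplicates removed.  Over the matched voxels' standardized
feature vectors an affinity graph is built — Pearson correlation across the
feature dimension with negative values clipped to zero — and the VB index is
the algebraic connectivity (second-smallest eigenvalue of the unnormalised
graph Laplacian ``L = D - W``) scaled by the node count, so a complete
unit-weight graph (perfect local homogeneity) scores exactly 1 and a
disconnected graph (a sharp feature transition) scores 0.

Neighbourhoods with fewer than ``min_neighbourhood`` voxels (default 3), or
whose centre voxel falls outside the mask, yield a missing value rather than
aborting the map.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry_io import FeatureVolume, SubjectRecord, SurfaceMesh, world_to_voxel

#: smallest usable affinity graph; below this the VB index is undefined
MIN_NEIGHBOURHOOD = 3


@dataclass
class VertexNeighbourhood:
    """Matched voxel set of one searchlight."""

    centre_vertex: int
    centre_voxel: tuple[int, int, int] | None
    voxel_list: np.ndarray        # (n, 3) int, deduplicated, masked
    feature_vectors: np.ndarray   # (n, C)
    usable: bool = True

    @property
    def size(self) -> int:
        return len(self.voxel_list)


@dataclass
class VBMap:
    values: np.ndarray            # (V,) in [0, 1] or NaN
    neighbourhood_sizes: np.ndarray
    metadata: dict = field(default_factory=dict)


def one_ring(mesh: SurfaceMesh, vertex: int) -> np.ndarray:
    """The vertex plus all vertices sharing a triangle edge with it."""
    if not (0 <= vertex < mesh.vertex_count):
        raise IndexError(f"vertex {vertex} out of range [0, {mesh.vertex_count})")
    return np.concatenate(([vertex], mesh.adjacency[vertex]))


def hybrid_neighbourhood(mesh: SurfaceMesh, vertex: int,
                         volume: FeatureVolume) -> VertexNeighbourhood:
    """Map the one-ring to nearest voxels, keep masked voxels within the
    27-voxel cube around the centre voxel, and deduplicate."""
    ring = one_ring(mesh, vertex)
    vox = world_to_voxel(volume.affine, mesh.vertex_coords[ring])
    centre = vox[0]
    shape = np.array(volume.mask.shape)
    if ((centre < 0).any() or (centre >= shape).any()
            or not volume.mask[tuple(centre)]):
        return VertexNeighbourhood(vertex, None, np.empty((0, 3), np.int64),
                                   np.empty((0, volume.n_channels)), usable=False)
    inside_cube = (np.abs(vox - centre) <= 1).all(axis=1)
    vox = vox[inside_cube]
    in_grid = ((vox >= 0) & (vox < shape)).all(axis=1)
    vox = vox[in_grid]
    vox = np.unique(vox, axis=0)
    masked = volume.mask[vox[:, 0], vox[:, 1], vox[:, 2]]
    vox = vox[masked]
    feats = volume.data[vox[:, 0], vox[:, 1], vox[:, 2]]
    return VertexNeighbourhood(vertex, tuple(centre), vox, feats, usable=True)


def affinity(x: np.ndarray, y: np.ndarray) -> float:
    """Edge weight: Pearson correlation across the feature dimension,
    clipped to [0, 1]; zero-variance vectors get affinity 0."""
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("feature vectors must be 1D and of equal length")
    if len(x) < 2:
        raise ValueError("feature vectors must have length >= 2")
    xc = x - x.mean()
    yc = y - y.mean()
    denom = np.linalg.norm(xc) * np.linalg.norm(yc)
    if denom == 0:
        return 0.0
    return float(np.clip(xc @ yc / denom, 0.0, 1.0))


def build_affinity_graph(neigh: VertexNeighbourhood) -> np.ndarray | None:
    """All-pairs affinity over the neighbourhood's feature vectors.

    Returns a symmetric non-negative matrix with zero diagonal, or None when
    the neighbourhood is unusable (fewer than MIN_NEIGHBOURHOOD voxels).
    """
    if not neigh.usable or neigh.size < MIN_NEIGHBOURHOOD:
        return None
    return _affinity_matrix(neigh.feature_vectors)


def _affinity_matrix(feats: np.ndarray) -> np.ndarray:
    xc = feats - feats.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(xc, axis=1)
    safe = np.where(norms == 0, 1.0, norms)
    r = (xc @ xc.T) / np.outer(safe, safe)
    r[norms == 0, :] = 0.0
    r[:, norms == 0] = 0.0
    w = np.clip(r, 0.0, 1.0)
    np.fill_diagonal(w, 0.0)
    return w


def algebraic_connectivity(weights: np.ndarray) -> float:
    """Second-smallest eigenvalue of the unnormalised Laplacian ``L = D - W``.

    Tiny negative eigenvalues above -1e-10 are clipped to zero; the matrix
    must be symmetric with zero diagonal.
    """
    w = np.asarray(weights, float)
    if w.ndim != 2 or w.shape[0] != w.shape[1] or w.shape[0] < 2:
        raise ValueError("weights must be a square matrix with n >= 2")
    if not np.allclose(w, w.T, atol=1e-12):
        raise ValueError("affinity matrix must be symmetric")
    lap = np.diag(w.sum(axis=1)) - w
    evals = np.linalg.eigvalsh(lap)
    lam2 = evals[1]
    if lam2 < -1e-10:
        raise ValueError(f"Laplacian produced eigenvalue {lam2} < -1e-10")
    return max(lam2, 0.0)


def vb_at_vertex(weights: np.ndarray | None) -> float:
    """VB = lambda_2 / n, clipped to [0, 1]; NaN for an unusable graph.

    Division by the node count is the unique linear scaling under which the
    maximally homogeneous graph — complete with unit weights, lambda_2 = n —
    scores exactly 1.
    """
    if weights is None or weights.shape[0] < MIN_NEIGHBOURHOOD:
        return float("nan")
    lam2 = algebraic_connectivity(weights)
    return float(np.clip(lam2 / weights.shape[0], 0.0, 1.0))


def vb_map(subject: SubjectRecord,
           min_neighbourhood: int = MIN_NEIGHBOURHOOD) -> VBMap:
    """The full searchlight sweep: one VB value per mesh vertex.

    Deterministic; per-vertex failures (unusable neighbourhoods) become
    missing values, never abort the map.
    """
    mesh = subject.mesh
    vol = subject.features
    values = np.full(mesh.vertex_count, np.nan)
    sizes = np.zeros(mesh.vertex_count, dtype=np.int64)
    # vectorized precomputation shared across vertices
    all_vox = world_to_voxel(vol.affine, mesh.vertex_coords)
    shape = np.array(vol.mask.shape)
    for v in range(mesh.vertex_count):
        ring = np.concatenate(([v], mesh.adjacency[v]))
        vox = all_vox[ring]
        centre = vox[0]
        if ((centre < 0).any() or (centre >= shape).any()
                or not vol.mask[tuple(centre)]):
            continue
        vox = vox[(np.abs(vox - centre) <= 1).all(axis=1)]
        vox = vox[((vox >= 0) & (vox < shape)).all(axis=1)]
        vox = np.unique(vox, axis=0)
        vox = vox[vol.mask[vox[:, 0], vox[:, 1], vox[:, 2]]]
        sizes[v] = len(vox)
        if len(vox) < max(min_neighbourhood, MIN_NEIGHBOURHOOD):
            continue
        feats = vol.data[vox[:, 0], vox[:, 1], vox[:, 2]]
        values[v] = vb_at_vertex(_affinity_matrix(feats))
    return VBMap(values=values, neighbourhood_sizes=sizes,
                 metadata={"subject_id": subject.subject_id,
                           "min_neighbourhood": int(min_neighbourhood)})
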