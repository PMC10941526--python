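"""Synthetic cohorts with known regional homogeneity structure.

The generator emulates the inputs of the cortical feature-gradient analysis:
a closed triangulated surface standing in for a hemisphere, a co-registered
multi-channel voxel volume of microstructural metrics, and a two-group cohort
with age (PMA) and sex covariates.

The cortex-like structure is piecewise: the surface is partitioned into
connected geodesic-Voronoi patches; voxels inherit the patch of their nearest
vertex and receive a per-patch mean feature vector plus i.i.d. Gaussian voxel
noise.  Patch means are mutually equidistant (a scaled simplex in feature
space), so transitions between patches are sharp while the interior of a
patch varies only through noise.  The group effect is a *reduction of the
local noise SD* (multiplicative factor ``homogeneity_boost``) applied to the
preterm group inside designated patches — i.e. more homogeneous local
microstructure, which is exactly the quantity the VB index measures.  PMA
enters as a linear per-channel shift and sex is assigned alternately, giving
the inference stage real covariate columns.
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass, replace

import numpy as np
import trimesh
from scipy import ndimage
from scipy.sparse import coo_matrix
from scipy.sparse.csgraph import connected_components
from scipy.spatial import cKDTree

from .features import stack_channels
from .geometry_io import CohortTable, FeatureVolume, SubjectRecord, SurfaceMesh


@dataclass(frozen=True)
class PatchLabeling:
    labels: np.ndarray        # (V,) int patch id
    patch_count: int
    seed_vertices: np.ndarray

    def boundary_vertices(self, mesh: SurfaceMesh) -> np.ndarray:
        """Vertices with a one-ring neighbour of another patch."""
        lab = self.labels
        out = [v for v in range(mesh.vertex_count)
               if np.any(lab[mesh.adjacency[v]] != lab[v])]
        return np.array(out, dtype=np.int64)

    def interior_vertices(self, mesh: SurfaceMesh, ring: int = 1) -> np.ndarray:
        """Vertices whose ``ring``-ball is single-patch."""
        lab = self.labels
        keep = []
        for v in range(mesh.vertex_count):
            ball = {v}
            frontier = {v}
            for _ in range(ring):
                frontier = {int(u) for w in frontier for u in mesh.adjacency[w]} - ball
                ball |= frontier
            if all(lab[u] == lab[v] for u in ball):
                keep.append(v)
        return np.array(keep, dtype=np.int64)


@dataclass(frozen=True)
class SimulationParams:
    """Study conditions for one simulated hemisphere cohort."""

    mesh_subdivisions: int = 2
    sphere_radius: float = 4.0          # mm; edge length ~1 mm at 2 subdivisions
    voxel_size: float = 1.0             # mm, isotropic
    patch_count: int = 6
    channel_count: int = 6
    patch_mean_separation: float = 3.0  # distance between patch mean vectors
    within_patch_sd: float = 1.0        # voxel noise SD
    homogeneity_boost: float = 0.5      # noise-SD multiplier in effect patches (preterm)
    effect_patches: tuple[int, ...] = (0, 1)
    n_per_group: int = 10
    pma_range: tuple[float, float] = (38.0, 43.0)  # weeks at scan
    pma_slope: tuple[float, ...] = (0.01, 0.02, 0.03, 0.04, 0.05, 0.06)
    rng_seed: int = 0

    def __post_init__(self):
        if self.within_patch_sd < 0:
            raise ValueError("within_patch_sd must be >= 0")
        if not (0 < self.homogeneity_boost <= 1):
            raise ValueError("homogeneity_boost must be in (0, 1]")
        if not set(self.effect_patches) <= set(range(self.patch_count)):
            raise ValueError("effect_patches must be a subset of patch ids")
        if len(self.pma_slope) != self.channel_count:
            raise ValueError("pma_slope must have one entry per channel")

    def with_(self, **kw) -> "SimulationParams":
        return replace(self, **kw)


def make_sphere_mesh(subdivisions: int, radius: float = 1.0) -> SurfaceMesh:
    """Icosphere: repeated 4-way subdivision of an icosahedron, vertices
    projected to ``radius``; vertex count is ``10 * 4**subdivisions + 2``."""
    if subdivisions < 0:
        raise ValueError("subdivisions must be >= 0")
    m = trimesh.creation.icosphere(subdivisions=subdivisions, radius=radius)
    return SurfaceMesh(np.asarray(m.vertices, float), np.asarray(m.faces, np.int64))


def make_lattice_mesh(nx: int, ny: int, spacing: float = 1.0) -> SurfaceMesh:
    """Regular planar triangulated lattice in the z = 0 plane.

    ``nx * ny`` vertices at ``spacing`` mm; each grid cell is split into two
    right triangles.  Used for smoothing-kernel checks where exact axis
    distances are needed.
    """
    if nx < 2 or ny < 2:
        raise ValueError("lattice needs at least 2x2 vertices")
    xs, ys = np.meshgrid(np.arange(nx), np.arange(ny), indexing="ij")
    coords = np.column_stack([xs.ravel() * spacing, ys.ravel() * spacing,
                              np.zeros(nx * ny)])
    tris = []
    for i in range(nx - 1):
        for j in range(ny - 1):
            a = i * ny + j
            b = (i + 1) * ny + j
            c = i * ny + (j + 1)
            d = (i + 1) * ny + (j + 1)
            tris.append((a, b, c))
            tris.append((b, d, c))
    return SurfaceMesh(coords, np.array(tris, dtype=np.int64))


def make_patch_labels(mesh: SurfaceMesh, patch_count: int,
                      rng_seed: int = 0) -> PatchLabeling:
    """Connected geodesic-Voronoi patches.

    Seeds come from farthest-point sampling on the edge graph (Euclidean edge
    weights); labels grow from all seeds simultaneously by Dijkstra so that
    every patch is connected by construction; distance ties go to the lowest
    patch id.
    """
    n = mesh.vertex_count
    if not (1 <= patch_count <= n):
        raise ValueError(f"patch_count must be in [1, {n}]")
    edges = mesh.edges()
    w = mesh.edge_lengths()
    adj: list[list[tuple[int, float]]] = [[] for _ in range(n)]
    for (a, b), d in zip(edges, w):
        adj[a].append((b, d))
        adj[b].append((a, d))

    rng = np.random.default_rng(rng_seed)
    seeds = [int(rng.integers(n))]
    mind = _sssp(adj, seeds[0], n)
    while len(seeds) < patch_count:
        nxt = int(np.argmax(mind))
        seeds.append(nxt)
        mind = np.minimum(mind, _sssp(adj, nxt, n))

    labels = np.full(n, -1, dtype=np.int64)
    dist = np.full(n, np.inf)
    heap = [(0.0, pid, s) for pid, s in enumerate(seeds)]
    heapq.heapify(heap)
    while heap:
        d, pid, v = heapq.heappop(heap)
        if labels[v] >= 0:
            continue
        labels[v] = pid
        dist[v] = d
        for u, du in adj[v]:
            if labels[u] < 0:
                heapq.heappush(heap, (d + du, pid, u))
    return PatchLabeling(labels=labels, patch_count=patch_count,
                         seed_vertices=np.array(seeds, dtype=np.int64))


def _sssp(adj, source: int, n: int) -> np.ndarray:
    dist = np.full(n, np.inf)
    dist[source] = 0.0
    heap = [(0.0, source)]
    while heap:
        d, v = heapq.heappop(heap)
        if d > dist[v]:
            continue
        for u, du in adj[v]:
            nd = d + du
            if nd < dist[u]:
                dist[u] = nd
                heapq.heappush(heap, (nd, u))
    return dist


def patch_mean_vectors(patch_count: int, channel_count: int,
                       separation: float) -> np.ndarray:
    """(P, C) mean feature vectors at mutual distance ``separation``.

    Scaled standard-basis vectors: ||a e_i - a e_j|| = a sqrt(2) for i != j.
    Requires patch_count <= channel_count.
    """
    if patch_count > channel_count:
        raise ValueError("patch_count must not exceed channel_count for "
                         "equidistant patch means")
    means = np.zeros((patch_count, channel_count))
    a = separation / np.sqrt(2.0)
    for p in range(patch_count):
        means[p, p] = a
    return means


def synth_subject(mesh: SurfaceMesh, labels: PatchLabeling,
                  params: SimulationParams, group: str, pma: float, sex: str,
                  rng_seed: int, subject_id: str = "sub-000") -> SubjectRecord:
    """One subject: voxel grid enclosing the mesh (margin >= 2 voxels), a
    one-voxel-dilated surface-shell mask, and per-voxel feature vectors.

    Channels are z-scored over the mask before being returned, mirroring the
    per-subject standardisation applied to real metric maps.
    """
    vs = params.voxel_size
    coords = mesh.vertex_coords
    margin = 2
    origin = np.floor(coords.min(axis=0) / vs).astype(int) - margin
    top = np.ceil(coords.max(axis=0) / vs).astype(int) + margin
    shape = tuple((top - origin + 1).tolist())
    affine = np.diag([vs, vs, vs, 1.0])
    affine[:3, 3] = origin * vs

    ijk = np.rint((coords - origin * vs) / vs).astype(int)
    if (ijk < 0).any() or (ijk >= np.array(shape)).any():
        raise ValueError("mesh extends outside the constructible grid")

    shell = np.zeros(shape, dtype=bool)
    shell[ijk[:, 0], ijk[:, 1], ijk[:, 2]] = True
    mask = ndimage.binary_dilation(shell, structure=np.ones((3, 3, 3), bool))

    vox_idx = np.argwhere(mask)
    centres = vox_idx * vs + origin * vs
    _, nearest = cKDTree(coords).query(centres)
    vox_patch = labels.labels[nearest]

    means = patch_mean_vectors(params.patch_count, params.channel_count,
                               params.patch_mean_separation)
    slope = np.asarray(params.pma_slope)
    rng = np.random.default_rng(rng_seed)
    noise = rng.standard_normal((len(vox_idx), params.channel_count))
    sd = np.full(len(vox_idx), params.within_patch_sd)
    if group == "preterm":
        boosted = np.isin(vox_patch, list(params.effect_patches))
        sd[boosted] *= params.homogeneity_boost
    values = means[vox_patch] + pma * slope + noise * sd[:, None]

    data = np.zeros(shape + (params.channel_count,))
    data[vox_idx[:, 0], vox_idx[:, 1], vox_idx[:, 2]] = values
    features = stack_channels(data, mask, affine, zscore=True)
    return SubjectRecord(subject_id=subject_id, group=group, pma_at_scan=pma,
                         sex=sex, mesh=mesh, features=features)


def synth_cohort(params: SimulationParams,
                 mesh: SurfaceMesh | None = None,
                 labels: PatchLabeling | None = None,
                 hemisphere: str = "L") -> tuple[CohortTable, PatchLabeling]:
    """A full two-group cohort plus its patch labelling (ground truth).

    The effect group (preterm) has its voxel-noise SD multiplied by
    ``homogeneity_boost`` inside ``effect_patches``; ``boost = 1`` yields a
    null cohort whose group labels are exchangeable by construction.  PMA is
    uniform over ``pma_range``, sex alternates, and each subject gets an
    independent child seed derived from ``rng_seed``.
    """
    if params.n_per_group < 2:
        raise ValueError("n_per_group must be >= 2")
    if mesh is None:
        mesh = make_sphere_mesh(params.mesh_subdivisions, params.sphere_radius)
    if labels is None:
        labels = make_patch_labels(mesh, params.patch_count, params.rng_seed)

    n_total = 2 * params.n_per_group
    rng = np.random.default_rng(params.rng_seed)
    pmas = rng.uniform(*params.pma_range, size=n_total)
    child_seeds = rng.integers(0, 2**31 - 1, size=n_total)

    subjects = []
    for i in range(n_total):
        group = "preterm" if i < params.n_per_group else "term"
        sex = "M" if i % 2 == 0 else "F"
        subjects.append(synth_subject(
            mesh, labels, params, group, float(pmas[i]), sex,
            int(child_seeds[i]), subject_id=f"sub-{i:03d}"))
    effect = np.flatnonzero(np.isin(labels.labels, list(params.effect_patches)))
    cohort = CohortTable(subjects=subjects, hemisphere=hemisphere,
                         effect_vertices=effect)
    return cohort, labels


def patches_are_connected(mesh: SurfaceMesh, labels: PatchLabeling) -> bool:
    """Flood-fill check that every patch forms one connected component."""
    edges = mesh.edges()
    lab = labels.labels
    for pid in range(labels.patch_count):
        members = np.flatnonzero(lab == pid)
        if len(members) == 0:
            return False
        keep = np.isin(edges, members).all(axis=1)
        sub = edges[keep]
        remap = {v: i for i, v in enumerate(members)}
        if len(sub):
            rows = [remap[a] for a in sub[:, 0]]
            cols = [remap[b] for b in sub[:, 1]]
            g = coo_matrix((np.ones(len(sub)), (rows, cols)),
                           shape=(len(members), len(members)))
            ncomp, _ = connected_components(g, directed=False)
        else:
            ncomp = len(members)
        if ncomp != 1:
            return False
    return True
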