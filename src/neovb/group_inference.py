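"""Vertex-wise group inference on smoothed homogeneity maps.

The comparison of interest is preterm vs. term controlling for PMA at scan
and sex: an ordinary-least-squares fit per vertex, one-sided contrasts in
both directions, threshold-free cluster enhancement (TFCE) of the t maps,
and family-wise error (FWE) correction through the permutation distribution
of the maximum TFCE statistic.  Permutations follow the Freedman-Lane
scheme: residuals of the nuisance-only model (intercept, PMA, sex) are
permuted across subjects, the nuisance fit is added back, and the full model
is refitted.  Significance over the two hemispheres uses the Sidak-corrected
alpha ``1 - (1 - alpha)**(1/m)``.

TFCE integrates ``extent**E * height**H * dh`` over the threshold ladder
``h = dh, 2*dh, ..., <= max``; extent is the surface area (barycentric
vertex areas) of the connected component, via one-ring connectivity, that
contains the vertex at that threshold.  Missing vertices are never
suprathreshold.  The integration runs top-down with an incremental
union-find so the cost is near-linear per permutation.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from itertools import combinations, permutations

import numpy as np
from numba import njit

from .geometry_io import CohortTable, SurfaceMesh

DEFAULT_N_PERM = 10_000
DEFAULT_ALPHA = 0.05
DEFAULT_N_HEMISPHERES = 2


@dataclass(frozen=True)
class TfceParams:
    """TFCE exponents and integration step.

    E = 1.0 and H = 2.0 are the established surface defaults; ``dh = None``
    means one hundredth of the map maximum, chosen per map.
    """

    E: float = 1.0
    H: float = 2.0
    dh: float | None = None
    n_steps: int = 100

    def __post_init__(self):
        if self.E <= 0 or self.H <= 0:
            raise ValueError("TFCE exponents must be positive")
        if self.dh is not None and self.dh <= 0:
            raise ValueError("dh must be positive")
        if self.n_steps < 1:
            raise ValueError("n_steps must be >= 1")


@dataclass
class GroupInferenceResult:
    t_map: np.ndarray                 # (V,) observed t, NaN where missing
    tfce_pos: np.ndarray              # TFCE of +t (first contrast direction)
    tfce_neg: np.ndarray              # TFCE of -t (opposite direction)
    p_pos: np.ndarray                 # FWE-corrected p per vertex, in (0, 1]
    p_neg: np.ndarray
    null_max_pos: np.ndarray          # permutation null of max TFCE
    null_max_neg: np.ndarray
    n_permutations: int
    rng_seed: int
    exhaustive: bool
    alpha_threshold: float

    def significance_mask(self, direction: str = "pos") -> np.ndarray:
        p = self.p_pos if direction == "pos" else self.p_neg
        with np.errstate(invalid="ignore"):
            return np.asarray(p < self.alpha_threshold) & np.isfinite(p)


# ---------------------------------------------------------------------------
# design
# ---------------------------------------------------------------------------

def design_from_cohort(cohort: CohortTable) -> tuple[np.ndarray, np.ndarray, list[str]]:
    """Design matrix (intercept, group, centred PMA, centred sex) and the
    group>0 contrast.  Group coding: preterm = 1, term = 0."""
    cohort.require_both_groups()
    group = np.array([1.0 if s.group == "preterm" else 0.0
                      for s in cohort.subjects])
    pma = np.array([s.pma_at_scan for s in cohort.subjects])
    sex = np.array([1.0 if s.sex == "F" else 0.0 for s in cohort.subjects])
    X = np.column_stack([np.ones(len(cohort)), group,
                         pma - pma.mean(), sex - sex.mean()])
    contrast = np.array([0.0, 1.0, 0.0, 0.0])
    return X, contrast, ["intercept", "group", "pma_centred", "sex_centred"]


def check_design(X: np.ndarray) -> int:
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        raise ValueError("design matrix is rank deficient")
    if X.shape[0] < X.shape[1] + 2:
        raise ValueError("need at least p + 2 subjects for error dof")
    return rank


# ---------------------------------------------------------------------------
# GLM t statistic
# ---------------------------------------------------------------------------

def glm_tstat(maps: np.ndarray, design: np.ndarray,
              contrast: np.ndarray) -> np.ndarray:
    """Per-vertex OLS t for ``contrast @ beta``; maps is subjects x vertices.

    Vertices with any missing subject value get a missing t.
    """
    Y = np.asarray(maps, float)
    X = np.asarray(design, float)
    c = np.asarray(contrast, float)
    rank = check_design(X)
    valid = np.isfinite(Y).all(axis=0)
    t = np.full(Y.shape[1], np.nan)
    if valid.any():
        t[valid] = _tstat_complete(Y[:, valid], X, c, rank)
    return t


def _tstat_complete(Y, X, c, rank):
    """t statistics on complete data; Y is subjects x vertices, no NaN."""
    pinv = np.linalg.pinv(X)
    beta = pinv @ Y
    resid = Y - X @ beta
    dof = X.shape[0] - rank
    sigma2 = (resid ** 2).sum(axis=0) / dof
    cvar = float(c @ np.linalg.inv(X.T @ X) @ c)
    se = np.sqrt(cvar * sigma2)
    num = c @ beta
    t = np.zeros_like(se)
    nz = se > 0
    t[nz] = num[nz] / se[nz]
    degenerate = ~nz & (num != 0)  # perfect fit: infinite evidence
    t[degenerate] = np.sign(num[degenerate]) * np.inf
    return t


# ---------------------------------------------------------------------------
# nuisance-map residualisation
# ---------------------------------------------------------------------------

def residualize_nuisance_map(maps: np.ndarray,
                             nuisance: np.ndarray) -> np.ndarray:
    """Regress a per-vertex nuisance map (e.g. sulcal depth) out of the
    subject maps, vertex by vertex, keeping the grand mean.

    At each vertex the across-subject map vector is regressed on
    (intercept, nuisance); the returned value is residual + intercept, i.e.
    ``y - b1 * (z - mean(z))``.  A constant nuisance at a vertex leaves that
    vertex untouched.
    """
    Y = np.asarray(maps, float)
    Z = np.asarray(nuisance, float)
    if Y.shape != Z.shape:
        raise ValueError("maps and nuisance must have identical shape")
    zc = Z - Z.mean(axis=0, keepdims=True)
    yc = Y - Y.mean(axis=0, keepdims=True)
    denom = (zc ** 2).sum(axis=0)
    with np.errstate(divide="ignore", invalid="ignore"):
        b1 = np.where(denom > 0, (zc * yc).sum(axis=0) / np.where(denom > 0, denom, 1.0), 0.0)
    return Y - b1[None, :] * zc


# ---------------------------------------------------------------------------
# TFCE
# ---------------------------------------------------------------------------

@njit(cache=False)
def _uf_find(parent, v):
    root = v
    while parent[root] != root:
        root = parent[root]
    while parent[v] != root:
        nxt = parent[v]
        parent[v] = root
        v = nxt
    return root


@njit(cache=False)
def _tfce_kernel(stat, order, edges, edge_order, edge_min, areas,
                 e_exp, h_exp, dh, nsteps, out):
    V = stat.shape[0]
    nE = edges.shape[0]
    parent = np.empty(V, np.int64)
    carea = np.zeros(V)
    vp = 0
    ep = 0
    for j in range(nsteps, 0, -1):
        h = j * dh
        while vp < V and stat[order[vp]] >= h:
            v = order[vp]
            parent[v] = v
            carea[v] = areas[v]
            vp += 1
        while ep < nE and edge_min[edge_order[ep]] >= h:
            e = edge_order[ep]
            ra = _uf_find(parent, edges[e, 0])
            rb = _uf_find(parent, edges[e, 1])
            if ra != rb:
                parent[rb] = ra
                carea[ra] += carea[rb]
            ep += 1
        hterm = h ** h_exp * dh
        for idx in range(vp):
            v = order[idx]
            r = _uf_find(parent, v)
            out[v] += carea[r] ** e_exp * hterm


@dataclass
class _TfceGeometry:
    edges: np.ndarray
    areas: np.ndarray


def tfce_geometry(mesh: SurfaceMesh) -> _TfceGeometry:
    return _TfceGeometry(edges=mesh.edges().astype(np.int64),
                         areas=mesh.vertex_areas())


def tfce(mesh: SurfaceMesh | _TfceGeometry, stat_map: np.ndarray,
         params: TfceParams = TfceParams()) -> np.ndarray:
    """Threshold-free cluster enhancement of a per-vertex statistic map.

    Missing (NaN) vertices are treated as minus infinity and can never join
    a suprathreshold component; their TFCE is 0.
    """
    geom = mesh if isinstance(mesh, _TfceGeometry) else tfce_geometry(mesh)
    stat = np.asarray(stat_map, float).copy()
    stat[~np.isfinite(stat)] = -np.inf
    out = np.zeros(stat.shape[0])
    smax = stat.max()
    if not np.isfinite(smax) or smax <= 0:
        return out
    if params.dh is not None:
        dh = params.dh
        nsteps = int(math.floor(smax / dh + 1e-9))
        if nsteps < 1:
            return out
    else:
        nsteps = params.n_steps
        dh = smax / nsteps
    order = np.argsort(-stat, kind="stable").astype(np.int64)
    edge_min = np.minimum(stat[geom.edges[:, 0]], stat[geom.edges[:, 1]])
    edge_order = np.argsort(-edge_min, kind="stable").astype(np.int64)
    _tfce_kernel(stat, order, geom.edges, edge_order, edge_min, geom.areas,
                 params.E, params.H, float(dh), nsteps, out)
    return out


# ---------------------------------------------------------------------------
# permutation inference
# ---------------------------------------------------------------------------

def sidak_threshold(alpha: float, m: int) -> float:
    """Per-test alpha controlling the family-wise level over m independent
    tests: ``1 - (1 - alpha)**(1/m)``."""
    if not (0 < alpha < 1):
        raise ValueError("alpha must be in (0, 1)")
    if m < 1:
        raise ValueError("m must be >= 1")
    return 1.0 - (1.0 - alpha) ** (1.0 / m)


def _canonical_order(design: np.ndarray) -> np.ndarray:
    """Stable row order determined by the design values alone, so results do
    not depend on the order subjects were listed in."""
    return np.lexsort(design.T[::-1])


def _distinct_relabelings(X, Z, contrast, n):
    """Number of permutations yielding distinct statistics."""
    tested = np.flatnonzero(np.asarray(contrast) != 0)
    nuisance_constant = all(np.allclose(Z[:, j], Z[0, j]) for j in range(Z.shape[1]))
    if nuisance_constant and len(tested) == 1:
        g = X[:, tested[0]]
        if np.isin(g, [0.0, 1.0]).all():
            k = int(g.sum())
            return math.comb(n, k), ("groups", k)
    return math.factorial(n), ("rows", None)


def permutation_fwe(maps: np.ndarray, design: np.ndarray, contrast: np.ndarray,
                    mesh: SurfaceMesh, n_perm: int = DEFAULT_N_PERM,
                    rng_seed: int = 0,
                    tfce_params: TfceParams = TfceParams(),
                    alpha: float = DEFAULT_ALPHA,
                    n_hemispheres: int = DEFAULT_N_HEMISPHERES) -> GroupInferenceResult:
    """Freedman-Lane permutation test with max-TFCE FWE correction.

    Both one-sided contrasts (``contrast`` and its negation) are computed in
    one run from the same permutations.  Corrected p-values follow the
    ``(b + 1) / (m + 1)`` convention; when ``n_perm`` reaches the number of
    distinct relabelings the test switches to exhaustive enumeration (the
    identity included) and p-values become exact.

    Subject rows are internally re-ordered into a canonical order derived
    from the design values, so permuting the input rows (maps and design
    together) leaves every output bit-identical.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Y = np.asarray(maps, float)
    X = np.asarray(design, float)
    c = np.asarray(contrast, float)
    if Y.shape[0] != X.shape[0]:
        raise ValueError("maps and design disagree on subject count")
    rank = check_design(X)

    order = _canonical_order(X)
    Y = Y[order]
    X = X[order]
    n = X.shape[0]

    tested = np.flatnonzero(c != 0)
    if len(tested) == 0:
        raise ValueError("contrast selects no column")
    Z = X[:, np.flatnonzero(c == 0)]

    valid = np.isfinite(Y).all(axis=0)
    geom = tfce_geometry(mesh)
    V = Y.shape[1]

    t_obs = np.full(V, np.nan)
    t_obs[valid] = _tstat_complete(Y[:, valid], X, c, rank)
    tfce_pos = tfce(geom, t_obs, tfce_params)
    tfce_neg = tfce(geom, -t_obs, tfce_params)

    # Freedman-Lane: permute residuals of the nuisance-only model
    Yv = Y[:, valid]
    Hz = Z @ np.linalg.pinv(Z)
    fitted = Hz @ Yv
    resid = Yv - fitted

    n_distinct, (scheme, k) = _distinct_relabelings(X, Z, c, n)
    exhaustive = n_perm >= n_distinct
    if exhaustive:
        if n_perm > n_distinct:
            warnings.warn(
                f"n_perm={n_perm} exceeds the {n_distinct} distinct "
                "relabelings; enumerating exhaustively instead")
        perms = _enumerate_perms(X, c, scheme, k, n)
        m_used = len(perms)
    else:
        rng = np.random.default_rng(rng_seed)
        perms = [rng.permutation(n) for _ in range(n_perm)]
        m_used = n_perm

    null_pos = np.empty(m_used)
    null_neg = np.empty(m_used)
    tf_full = np.full(V, np.nan)
    for j, pi in enumerate(perms):
        Ystar = fitted + resid[pi]
        tstar = _tstat_complete(Ystar, X, c, rank)
        tf_full[:] = np.nan
        tf_full[valid] = tstar
        null_pos[j] = tfce(geom, tf_full, tfce_params).max()
        null_neg[j] = tfce(geom, -tf_full, tfce_params).max()

    p_pos = np.full(V, np.nan)
    p_neg = np.full(V, np.nan)
    if exhaustive:
        p_pos[valid] = (null_pos[None, :] >= tfce_pos[valid, None]).sum(axis=1) / m_used
        p_neg[valid] = (null_neg[None, :] >= tfce_neg[valid, None]).sum(axis=1) / m_used
    else:
        p_pos[valid] = (1 + (null_pos[None, :] >= tfce_pos[valid, None]).sum(axis=1)) / (m_used + 1)
        p_neg[valid] = (1 + (null_neg[None, :] >= tfce_neg[valid, None]).sum(axis=1)) / (m_used + 1)

    return GroupInferenceResult(
        t_map=t_obs, tfce_pos=tfce_pos, tfce_neg=tfce_neg,
        p_pos=p_pos, p_neg=p_neg,
        null_max_pos=null_pos, null_max_neg=null_neg,
        n_permutations=m_used, rng_seed=rng_seed, exhaustive=exhaustive,
        alpha_threshold=sidak_threshold(alpha, n_hemispheres))


def _enumerate_perms(X, c, scheme, k, n):
    if scheme == "groups":
        g = X[:, np.flatnonzero(c != 0)[0]]
        ones = np.flatnonzero(g == 1.0)
        zeros = np.flatnonzero(g == 0.0)
        perms = []
        for chosen in combinations(range(n), k):
            chosen = list(chosen)
            rest = [i for i in range(n) if i not in set(chosen)]
            pi = np.empty(n, dtype=np.int64)
            pi[ones] = chosen          # residual rows assigned to group-1 slots
            pi[zeros] = rest
            perms.append(pi)
        return perms
    return [np.array(p, dtype=np.int64) for p in permutations(range(n))]
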