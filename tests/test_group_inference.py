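import numpy as np
import pytest
from scipy import sparse, stats
from scipy.sparse.csgraph import connected_components

from neovb import (glm_tstat, permutation_fwe, residualize_nuisance_map,
                   sidak_threshold, tfce)
from neovb.group_inference import TfceParams, check_design
from neovb.synthetic_data import make_lattice_mesh


class TestSidak:
    def test_single_test_is_identity(self):
        assert sidak_threshold(0.05, 1) == pytest.approx(0.05)

    def test_four_way_closed_form(self):
        assert sidak_threshold(0.05, 4) == pytest.approx(1 - 0.95 ** 0.25,
                                                         abs=1e-12)

    @pytest.mark.parametrize("alpha,m", [(0.0, 2), (1.0, 2), (0.5, 0)])
    def test_invalid_inputs_raise(self, alpha, m):
        with pytest.raises(ValueError):
            sidak_threshold(alpha, m)


class TestResidualize:
    def test_nuisance_equal_to_map_removes_variance(self):
        rng = np.random.default_rng(20)
        maps = rng.normal(size=(8, 5))
        out = residualize_nuisance_map(maps, maps.copy())
        np.testing.assert_allclose(out, maps.mean(axis=0, keepdims=True)
                                   * np.ones((8, 1)), atol=1e-10)

    def test_orthogonal_nuisance_leaves_map(self):
        maps = np.outer([1.0, -1.0, 1.0, -1.0], np.ones(3))
        nuis = np.outer([1.0, 1.0, -1.0, -1.0], np.ones(3))
        out = residualize_nuisance_map(maps, nuis)
        np.testing.assert_allclose(out, maps, atol=1e-10)

    def test_constant_nuisance_is_identity(self):
        rng = np.random.default_rng(21)
        maps = rng.normal(size=(5, 4))
        out = residualize_nuisance_map(maps, np.ones((5, 4)))
        np.testing.assert_array_equal(out, maps)

    def test_four_subject_worked_case_matches_lstsq(self):
        y = np.array([2.0, 4.0, 5.0, 9.0])
        z = np.array([1.0, 2.0, 3.0, 4.0])
        X = np.column_stack([np.ones(4), z])
        beta, *_ = np.linalg.lstsq(X, y, rcond=None)
        expected = y - beta[1] * (z - z.mean())
        out = residualize_nuisance_map(y[:, None], z[:, None])
        np.testing.assert_allclose(out.ravel(), expected, atol=1e-10)
        assert np.isclose(out.mean(), y.mean())  # grand mean preserved


class TestGlmTstat:
    def test_equals_two_sample_pooled_t(self):
        rng = np.random.default_rng(22)
        g = np.repeat([1.0, 0.0], 5)
        X = np.column_stack([np.ones(10), g])
        y = rng.normal(size=(10, 7))
        t = glm_tstat(y, X, np.array([0.0, 1.0]))
        for v in range(7):
            expected = stats.ttest_ind(y[:5, v], y[5:, v],
                                       equal_var=True).statistic
            assert np.isclose(t[v], expected, atol=1e-10)

    def test_zero_contrast_gives_zero(self):
        rng = np.random.default_rng(23)
        X = np.column_stack([np.ones(8), np.repeat([1.0, 0.0], 4)])
        t = glm_tstat(rng.normal(size=(8, 3)), X, np.zeros(2))
        np.testing.assert_array_equal(t, 0.0)

    def test_six_subject_fixture_matches_normal_equations(self):
        rng = np.random.default_rng(24)
        X = np.column_stack([np.ones(6), [1, 1, 1, 0, 0, 0],
                             rng.normal(size=6)])
        y = rng.normal(size=(6, 4))
        c = np.array([0.0, 1.0, 0.0])
        t = glm_tstat(y, X, c)
        XtXinv = np.linalg.inv(X.T @ X)
        for v in range(4):
            beta = XtXinv @ X.T @ y[:, v]
            resid = y[:, v] - X @ beta
            s2 = resid @ resid / (6 - 3)
            expected = (c @ beta) / np.sqrt(c @ XtXinv @ c * s2)
            assert np.isclose(t[v], expected, atol=1e-10)

    def test_missing_subject_value_gives_missing_t(self):
        rng = np.random.default_rng(25)
        X = np.column_stack([np.ones(8), np.repeat([1.0, 0.0], 4)])
        y = rng.normal(size=(8, 3))
        y[2, 1] = np.nan
        t = glm_tstat(y, X, np.array([0.0, 1.0]))
        assert np.isnan(t[1]) and np.isfinite(t[[0, 2]]).all()

    def test_rank_deficient_design_raises(self):
        X = np.column_stack([np.ones(6), np.ones(6)])
        with pytest.raises(ValueError, match="rank"):
            check_design(X)


@pytest.fixture(scope="module")
def lattice8():
    return make_lattice_mesh(8, 8, spacing=1.0)


@pytest.fixture(scope="module")
def lattice43():
    return make_lattice_mesh(4, 3, spacing=1.0)


def tfce_oracle(mesh, stat, E, H, n_steps=100):
    """Brute-force TFCE: explicit component search at every threshold."""
    stat = np.where(np.isfinite(stat), stat, -np.inf)
    areas = mesh.vertex_areas()
    edges = mesh.edges()
    out = np.zeros(mesh.vertex_count)
    smax = stat.max()
    if smax <= 0:
        return out
    dh = smax / n_steps
    for j in range(1, n_steps + 1):
        h = j * dh
        active = stat >= h
        keep = active[edges].all(axis=1)
        sub = edges[keep]
        n = mesh.vertex_count
        g = sparse.coo_matrix((np.ones(len(sub)),
                               (sub[:, 0], sub[:, 1])), shape=(n, n))
        ncomp, lab = connected_components(g + g.T, directed=False)
        for comp in range(ncomp):
            members = np.flatnonzero((lab == comp) & active)
            if len(members) == 0:
                continue
            extent = areas[members].sum()
            out[members] += extent ** E * h ** H * dh
    return out


class TestTfce:
    def test_zero_map_gives_zero(self, lattice8):
        mesh = lattice8
        out = tfce(mesh, np.zeros(mesh.vertex_count))
        np.testing.assert_array_equal(out, 0.0)

    def test_single_vertex_height_integration(self, lattice8):
        """One suprathreshold vertex: TFCE equals its area times the direct
        height sum."""
        mesh = lattice8
        stat = np.zeros(mesh.vertex_count)
        stat[27] = 2.0
        out = tfce(mesh, stat, TfceParams(E=1.0, H=2.0))
        dh = 2.0 / 100
        expected = mesh.vertex_areas()[27] * sum(
            (j * dh) ** 2 * dh for j in range(1, 101))
        assert np.isclose(out[27], expected, rtol=1e-10)
        assert out[np.arange(len(out)) != 27].max() == 0.0

    def test_matches_bruteforce_oracle(self, lattice8):
        mesh = lattice8
        rng = np.random.default_rng(26)
        stat = rng.normal(size=mesh.vertex_count)
        for E, H in [(1.0, 2.0), (0.5, 2.0), (2.0, 0.5)]:
            mine = tfce(mesh, stat, TfceParams(E=E, H=H))
            oracle = tfce_oracle(mesh, stat, E, H)
            np.testing.assert_allclose(mine, oracle, rtol=1e-9, atol=1e-12)

    def test_missing_values_never_suprathreshold(self, lattice8):
        mesh = lattice8
        rng = np.random.default_rng(27)
        stat = rng.uniform(0.5, 1.0, size=mesh.vertex_count)
        stat[10] = np.nan
        out = tfce(mesh, stat)
        assert out[10] == 0.0
        oracle = tfce_oracle(mesh, stat, 1.0, 2.0)
        np.testing.assert_allclose(out, oracle, rtol=1e-9, atol=1e-12)

    def test_monotone_in_the_statistic(self, lattice8):
        mesh = lattice8
        rng = np.random.default_rng(28)
        stat = rng.normal(size=mesh.vertex_count)
        base = tfce(mesh, stat, TfceParams(dh=0.05))
        bumped = stat.copy()
        bumped[20] += 0.5
        out = tfce(mesh, bumped, TfceParams(dh=0.05))
        assert (out >= base - 1e-12).all()

    def test_invalid_params_raise(self):
        with pytest.raises(ValueError):
            TfceParams(E=0.0)
        with pytest.raises(ValueError):
            TfceParams(dh=-1.0)


class TestPermutationFwe:
    def _cohort(self, mesh, n_per_group=3, seed=29, covariates=False):
        rng = np.random.default_rng(seed)
        n = 2 * n_per_group
        g = np.repeat([1.0, 0.0], n_per_group)
        cols = [np.ones(n), g]
        if covariates:
            cols += [rng.normal(size=n)]
        X = np.column_stack(cols)
        c = np.zeros(X.shape[1])
        c[1] = 1.0
        maps = rng.normal(size=(n, mesh.vertex_count))
        return maps, X, c

    def test_p_values_bounded(self, lattice43):
        mesh = lattice43
        maps, X, c = self._cohort(mesh, n_per_group=5)
        res = permutation_fwe(maps, X, c, mesh, n_perm=99, rng_seed=1)
        p = np.concatenate([res.p_pos, res.p_neg])
        assert np.nanmin(p) >= 1.0 / 100
        assert np.nanmax(p) <= 1.0

    def test_exhaustive_matches_direct_enumeration(self, lattice43):
        mesh = lattice43
        """20 relabelings of a 6-subject toy: p-values agree with explicit
        two-sample enumeration."""
        from itertools import combinations
        maps, X, c = self._cohort(mesh, n_per_group=3)
        with pytest.warns(UserWarning, match="distinct"):
            res = permutation_fwe(maps, X, c, mesh, n_perm=500, rng_seed=0)
        assert res.exhaustive and res.n_permutations == 20

        null_max = []
        for chosen in combinations(range(6), 3):
            g = np.zeros(6)
            g[list(chosen)] = 1.0
            t = np.array([stats.ttest_ind(maps[g == 1, v], maps[g == 0, v],
                                          equal_var=True).statistic
                          for v in range(mesh.vertex_count)])
            null_max.append(tfce(mesh, t).max())
        null_max = np.array(null_max)
        p_oracle = (null_max[None, :] >= res.tfce_pos[:, None]).sum(axis=1) / 20
        np.testing.assert_allclose(res.p_pos, p_oracle, atol=1e-12)

    def test_minimal_p_attained_by_strong_effect(self, lattice43):
        mesh = lattice43
        rng = np.random.default_rng(30)
        n = 12
        g = np.repeat([1.0, 0.0], 6)
        X = np.column_stack([np.ones(n), g])
        maps = rng.normal(size=(n, mesh.vertex_count)) * 0.01
        maps[g == 1] += 5.0
        res = permutation_fwe(maps, X, np.array([0.0, 1.0]), mesh,
                              n_perm=199, rng_seed=2)
        assert np.nanmin(res.p_pos) == pytest.approx(1.0 / 200)

    def test_subject_order_invariance_bit_identical(self, lattice43):
        mesh = lattice43
        """Permuting subject rows (maps and design together) leaves every
        output unchanged."""
        maps, X, c = self._cohort(mesh, n_per_group=4, covariates=True)
        res_a = permutation_fwe(maps, X, c, mesh, n_perm=50, rng_seed=3)
        rng = np.random.default_rng(31)
        pi = rng.permutation(len(maps))
        res_b = permutation_fwe(maps[pi], X[pi], c, mesh, n_perm=50, rng_seed=3)
        np.testing.assert_array_equal(res_a.t_map, res_b.t_map)
        np.testing.assert_array_equal(res_a.p_pos, res_b.p_pos)
        np.testing.assert_array_equal(res_a.null_max_pos, res_b.null_max_pos)

    def test_missing_vertex_propagates(self, lattice43):
        mesh = lattice43
        maps, X, c = self._cohort(mesh, n_per_group=4)
        maps[0, 5] = np.nan
        res = permutation_fwe(maps, X, c, mesh, n_perm=30, rng_seed=4)
        assert np.isnan(res.t_map[5]) and np.isnan(res.p_pos[5])
        assert np.isfinite(np.delete(res.t_map, 5)).all()
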