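"""Group ICA: MDL, staged PCA, Infomax, ICASSO, back-reconstruction, matching."""

import numpy as np
import pytest

from restconn import gica, synthio
from restconn.errors import RankError, ValidationError
from restconn.grid import VolumeGrid
from restconn.prep import FmriSession


def _toy_sessions(n_sessions, t, v, rank, seed):
    """Sessions sharing a planted low-rank structure plus noise."""
    rng = np.random.default_rng(seed)
    maps = rng.standard_normal((rank, v))
    grid = VolumeGrid((v, 1, 1))
    sessions = []
    for i in range(n_sessions):
        tcs = rng.standard_normal((t, rank))
        data = tcs @ maps * 3 + rng.standard_normal((t, v))
        sessions.append(
            FmriSession(f"sub-{i:03d}", "abstinence", grid, 2.0, data.T.reshape(v, 1, 1, t))
        )
    return sessions


class TestComponentCount:
    def test_planted_components_recovered(self, rng):
        mix = rng.standard_normal((5, 20))
        data = rng.standard_normal((2000, 5)) @ mix * 3 + rng.standard_normal((2000, 20))
        assert gica.estimate_component_count(data) == 5

    def test_equal_eigenvalues_give_zero(self):
        # all-equal spectrum: the likelihood term vanishes for every k and the
        # parameter penalty is minimised at k = 0
        curve = gica.mdl_curve(np.ones(12), n_obs=500)
        assert int(np.argmin(curve)) == 0

    def test_duplicate_variable_raises_rank_error(self, rng):
        x = rng.standard_normal((100, 4))
        data = np.column_stack([x, x[:, 0]])
        with pytest.raises(RankError):
            gica.estimate_component_count(data)


class TestStagewisePca:
    def test_single_session_collapses_to_plain_pca(self):
        sessions = _toy_sessions(1, 60, 50, 4, seed=0)
        reduced, proj = gica.reduce_stagewise_pca(sessions, (6, 6, 6), block_size=7)
        x, _ = gica.session_matrix(sessions[0])
        # plain PCA to 6 dimensions spans the same subspace
        u = gica._top_rows(x, 6)
        direct = u @ x
        # round-trip through the stored projections reproduces the retained part
        back = proj.session_proj[0].T @ (
            proj.block_proj[0].T @ (proj.final_proj.T @ reduced)
        )
        recon_direct = u.T @ direct
        np.testing.assert_allclose(back, recon_direct, atol=1e-8)

    def test_exact_rank_data_fully_explained(self):
        rng = np.random.default_rng(3)
        grid = VolumeGrid((40, 1, 1))
        maps = rng.standard_normal((3, 40))
        sessions = []
        for i in range(4):
            tcs = rng.standard_normal((30, 3))
            data = (tcs @ maps).T.reshape(40, 1, 1, 30)
            sessions.append(FmriSession(f"s{i}", "abstinence", grid, 2.0, data))
        reduced, proj = gica.reduce_stagewise_pca(sessions, (5, 4, 3), block_size=2)
        for i, ses in enumerate(sessions):
            x, _ = gica.session_matrix(ses)
            f = proj.session_proj[i]
            residual = x - f.T @ (f @ x)
            assert np.abs(residual).max() < 1e-8

    def test_output_shape_for_42_sessions(self):
        sessions = _toy_sessions(42, 45, 30, 3, seed=1)
        reduced, _ = gica.reduce_stagewise_pca(sessions, (40, 30, 23), block_size=7)
        assert reduced.shape == (23, 30)

    def test_dim_ordering_enforced(self):
        sessions = _toy_sessions(2, 40, 20, 2, seed=2)
        with pytest.raises(ValidationError):
            gica.reduce_stagewise_pca(sessions, (10, 20, 5))


def _match_rows(recovered, truth):
    """Greedy |corr| matching; returns matched |corr| per truth row."""
    c = np.abs(np.corrcoef(np.vstack([recovered, truth]))[: len(recovered), len(recovered):])
    out = []
    used = set()
    for j in range(truth.shape[0]):
        order = np.argsort(-c[:, j])
        for i in order:
            if i not in used:
                used.add(i)
                out.append(c[i, j])
                break
    return np.array(out)


class TestInfomax:
    def test_laplacian_sources_recovered(self, rng):
        s = rng.laplace(size=(2, 5000))
        mixed = rng.standard_normal((2, 2)) @ s
        result = gica.infomax_ica(mixed, seed=0)
        assert result.converged
        matched = _match_rows(result.spatial_maps, s)
        assert np.all(matched >= 0.99)

    def test_already_unmixed_input_gives_signed_permutation(self, rng):
        s = rng.laplace(size=(2, 5000))
        result = gica.infomax_ica(s, seed=0)
        c = np.corrcoef(np.vstack([result.spatial_maps, s]))[:2, 2:]
        # after matching, off-diagonal couplings are negligible
        perm = np.abs(c)
        best = perm.argmax(axis=1)
        assert sorted(best) == [0, 1]
        for i, j in enumerate(best):
            off = perm[i, 1 - j]
            assert off < 0.05

    def test_gaussian_sources_flagged_nonidentifiable(self, rng):
        result = gica.infomax_ica(rng.standard_normal((2, 4000)), seed=0)
        assert not result.identifiable

    def test_amari_index_small_on_identifiable_toy(self, rng):
        k = 3
        s = rng.laplace(size=(k, 6000))
        a = rng.standard_normal((k, k))
        result = gica.infomax_ica(a @ s, seed=2)
        # global system = unmixing composed with mixing, scale-normalised
        g = np.abs(result.unmixing @ a * s.std(axis=1))
        g = g / g.max(axis=1, keepdims=True)
        amari = 0.0
        for i in range(k):
            amari += g[i].sum() / g[i].max() - 1
            amari += g[:, i].sum() / g[:, i].max() - 1
        amari /= 2 * k * (k - 1)
        assert amari < 0.05

    def test_sign_convention_nonnegative_skewness(self, rng):
        s = np.abs(rng.laplace(size=(2, 4000)))  # strongly right-skewed sources
        result = gica.infomax_ica(rng.standard_normal((2, 2)) @ s, seed=1)
        mc = result.spatial_maps - result.spatial_maps.mean(axis=1, keepdims=True)
        assert np.all((mc**3).mean(axis=1) >= 0)


class TestIcasso:
    def _runs_from(self, maps, n):
        k = maps.shape[0]
        return [
            gica.ComponentSet(maps.copy(), np.eye(k), np.eye(k), k) for _ in range(n)
        ]

    @staticmethod
    def _orthogonal_maps(k, v):
        # zero-mean mutually uncorrelated maps: cross-cluster similarity is 0
        t = np.arange(v)
        return np.stack([np.sin(2 * np.pi * (f + 1) * t / v) for f in range(k)])

    def test_identical_runs_give_stability_one(self):
        maps = self._orthogonal_maps(3, 500)
        selected, stability = gica.icasso_select(self._runs_from(maps, 20), 3)
        np.testing.assert_allclose(stability, 1.0, atol=1e-10)
        matched = _match_rows(selected.spatial_maps, maps)
        assert np.all(matched >= 0.999999)

    def test_sign_flips_cluster_together(self):
        maps = self._orthogonal_maps(2, 500)
        run1 = gica.ComponentSet(maps.copy(), np.eye(2), np.eye(2), 2)
        run2 = gica.ComponentSet(-maps.copy(), np.eye(2), np.eye(2), 2)
        _, stability = gica.icasso_select([run1, run2], 2)
        np.testing.assert_allclose(stability, 1.0, atol=1e-10)

    def test_count_mismatch_rejected(self, rng):
        r1 = gica.ComponentSet(rng.standard_normal((2, 100)), np.eye(2), np.eye(2), 2)
        r2 = gica.ComponentSet(rng.standard_normal((3, 100)), np.eye(3), np.eye(3), 3)
        with pytest.raises(ValidationError):
            gica.icasso_select([r1, r2], 2)

    def test_centrotypes_recover_laplacian_sources(self, rng):
        s = rng.laplace(size=(2, 4000))
        mixed = rng.standard_normal((2, 2)) @ s
        runs = [gica.infomax_ica(mixed, seed=i) for i in range(20)]
        selected, stability = gica.icasso_select(runs, 2)
        matched = _match_rows(selected.spatial_maps, s)
        assert np.all(matched >= 0.99)
        assert np.all(stability > 0.9)


class TestBackReconstruction:
    def test_single_session_subject_maps_equal_group_maps(self):
        sessions = _toy_sessions(1, 80, 60, 3, seed=4)
        result = gica.group_ica(sessions, n_components=3, n_runs=3, seed=0,
                                stage_dims=(3, 3, 3), block_size=1)
        for k in range(3):
            r = np.corrcoef(result.subject_maps[0][k], result.group.spatial_maps[k])[0, 1]
            assert abs(r) >= 0.999

    def test_determinism_of_full_decomposition(self):
        sessions = _toy_sessions(4, 40, 50, 3, seed=5)
        a = gica.group_ica(sessions, 3, n_runs=4, seed=7, stage_dims=(6, 5, 3), block_size=2)
        b = gica.group_ica(sessions, 3, n_runs=4, seed=7, stage_dims=(6, 5, 3), block_size=2)
        np.testing.assert_array_equal(a.group.spatial_maps, b.group.spatial_maps)
        np.testing.assert_array_equal(a.stability, b.stability)

    def test_session_count_mismatch_rejected(self):
        sessions = _toy_sessions(2, 40, 30, 2, seed=6)
        _, proj = gica.reduce_stagewise_pca(sessions, (4, 4, 2), block_size=2)
        cs = gica.ComponentSet(np.zeros((2, 30)) + [[1.0] * 30, [2.0] * 30],
                               np.eye(2), np.eye(2), 2)
        with pytest.raises(ValidationError):
            gica.back_reconstruct(cs, proj, sessions[:1])


class TestTemplateMatching:
    @pytest.fixture
    def templates(self):
        grid = synthio.default_grid()
        return synthio.make_network_templates(
            grid,
            [((-15.0, 0.0, 0.0), 12.0, 1.0, "left"), ((15.0, 0.0, 0.0), 12.0, 1.0, "right")],
        )

    def test_identical_map_scores_one(self, templates):
        maps = templates.masks.reshape(2, -1).astype(float)
        match = gica.match_components(maps, templates, 0.3)
        assert match.assignments == {"left": 0, "right": 1}
        assert match.scores["left"] == pytest.approx(1.0)

    def test_random_map_stays_unmatched(self, templates, rng):
        v = templates.grid.n_voxels
        maps = rng.standard_normal((2, v))
        match = gica.match_components(maps, templates, threshold=0.3)
        assert set(match.unmatched) == {"left", "right"}
        for s in match.scores.values():
            assert abs(s) < 0.1

    def test_tie_broken_toward_lower_index(self, templates):
        template_map = templates.masks.reshape(2, -1).astype(float)[0]
        maps = np.stack([template_map, template_map, np.roll(template_map, 1)])
        match = gica.match_components(maps, templates, 0.01)
        assert match.assignments["left"] == 0
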