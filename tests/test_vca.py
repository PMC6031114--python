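"""Vertex component analysis: extraction, abundances, invariants."""

import numpy as np
import pytest

import ramanmix as rm
from ramanmix.vca import VcaOptions, vca_abundances, vca_extract


def _simplex_data(k=3, n=60, seed=0, margin=0.85, m=40, scale=100.0):
    """Noiseless simplex mixtures with planted pure pixels.

    Interior pixels are kept away from the vertices (max abundance <=
    ``margin``) so the simplex has exactly k vertices among the pixels.
    """
    rng = np.random.default_rng(seed)
    S = rng.random((k, m)) + 0.1
    C = rng.dirichlet(np.full(k, 2.0), size=n)
    C = np.where(C.max(1, keepdims=True) > margin,
                 (C + 1.0) / (C + 1.0).sum(1, keepdims=True), C)
    C[:k] = np.eye(k)
    return C @ S * scale, S, C


def _brute_force_vertices(D, tol=1e-6):
    """Pixels outside the convex hull of the others (simplex vertices).

    Membership is tested by non-negative least squares with an augmented
    closure row, an independent route from the projection-based search.
    """
    from scipy.optimize import nnls

    n = D.shape[0]
    alpha = 10.0 * np.abs(D).max()
    verts = []
    for i in range(n):
        others = np.delete(D, i, axis=0)
        A = np.vstack([others.T, alpha * np.ones(n - 1)])
        b = np.concatenate([D[i], [alpha]])
        _, resid = nnls(A, b)
        if resid > tol * np.linalg.norm(D[i]):
            verts.append(i)
    return set(verts)


class TestExtract:
    def test_orthogonal_pure_classes(self):
        D = np.repeat(np.eye(3), 10, axis=0) * 5.0
        idx, S = vca_extract(D, VcaOptions(rank=3, seed=0))
        np.testing.assert_allclose(sorted(S.max(axis=1)), [5, 5, 5])
        assert {tuple(np.nonzero(s)[0]) for s in S} == {(0,), (1,), (2,)}

    def test_selects_planted_pure_pixels(self):
        D, S, C = _simplex_data()
        idx, Se = vca_extract(D, VcaOptions(rank=3, seed=1))
        assert set(idx) <= {0, 1, 2}
        _, r, _ = rm.match_endmembers(S, Se)
        assert min(r) >= 0.999

    @pytest.mark.parametrize("k,n", [(2, 40), (3, 60), (4, 200)])
    def test_matches_brute_force_vertex_oracle(self, k, n):
        D, S, C = _simplex_data(k=k, n=n, seed=k + n)
        oracle = _brute_force_vertices(D)
        idx, _ = vca_extract(D, VcaOptions(rank=k, seed=5))
        assert set(idx) == oracle

    def test_endmembers_are_pixel_spectra(self, spruce_scene):
        D = spruce_scene.image.D
        idx, S = vca_extract(D, VcaOptions(rank=4, seed=2))
        for i, s in zip(idx, S):
            np.testing.assert_array_equal(s, D[i])

    def test_deterministic(self, spruce_scene):
        a = rm.run_vca(spruce_scene.image.D, VcaOptions(rank=4, seed=9))
        b = rm.run_vca(spruce_scene.image.D, VcaOptions(rank=4, seed=9))
        np.testing.assert_array_equal(a.S, b.S)
        np.testing.assert_array_equal(a.C, b.C)

    def test_permutation_equivariance(self):
        D, _, _ = _simplex_data(seed=4)
        rng = np.random.default_rng(0)
        perm = rng.permutation(D.shape[0])
        idx_a, _ = vca_extract(D, VcaOptions(rank=3, seed=7))
        idx_b, _ = vca_extract(D[perm], VcaOptions(rank=3, seed=7))
        assert [int(np.nonzero(perm == i)[0][0]) for i in idx_a] == list(idx_b)

    def test_rank_one(self):
        D, _, _ = _simplex_data(seed=2)
        res = rm.run_vca(D, VcaOptions(rank=1, seed=0))
        norms = np.linalg.norm(D, axis=1)
        assert np.linalg.norm(res.S[0]) == pytest.approx(norms.max())
        np.testing.assert_allclose(res.C, 1.0)


class TestAbundances:
    def test_pure_pixels_get_identity_rows(self):
        S = np.array([[1.0, 0.0, 2.0], [0.0, 3.0, 1.0]])
        C, flagged = vca_abundances(S, S)
        np.testing.assert_allclose(C, np.eye(2), atol=1e-10)
        assert flagged == []

    @pytest.mark.parametrize("mode", ["nnls_closure", "closure_only"])
    def test_exact_mixture_recovered(self, mode):
        rng = np.random.default_rng(3)
        S = rng.random((2, 30)) + 0.2
        d = 0.25 * S[0] + 0.75 * S[1]
        C, _ = vca_abundances(d[None, :], S, mode)
        np.testing.assert_allclose(C[0], [0.25, 0.75], atol=1e-8)

    def test_zero_pixel_uniform_and_flagged(self):
        S = np.array([[1.0, 0.0], [0.0, 1.0]])
        C, flagged = vca_abundances(np.zeros((1, 2)), S)
        np.testing.assert_allclose(C[0], [0.5, 0.5])
        assert flagged == [0]

    def test_closure_invariant(self, spruce_scene):
        res = rm.run_vca(spruce_scene.image.D, VcaOptions(rank=4, seed=1))
        np.testing.assert_allclose(res.C.sum(axis=1), 1.0, atol=1e-6)

    def test_rank_deficient_spectra_rejected(self):
        S = np.vstack([np.ones(10), 2.0 * np.ones(10)])
        with pytest.raises(ValueError, match="rank deficient"):
            vca_abundances(np.ones((3, 10)), S)


class TestOnScenes:
    def test_noiseless_spruce_recovery(self, spruce_scene):
        res = rm.run_vca(spruce_scene.image.D, VcaOptions(rank=4, seed=0))
        _, r, _ = rm.match_endmembers(spruce_scene.S_true, res.S)
        assert min(r) >= 0.99

    def test_runs_on_baseline_corrected_data(self):
        """Background-subtracted spectra dip below zero; VCA still runs and
        its endmembers remain pixel spectra of that data."""
        scene = rm.make_scene("spruce", (12, 12), snr=30,
                              background="poly3_mix", seed=3)
        corrected, _ = rm.subtract_baseline(scene.image)
        assert corrected.D.min() < 0
        res = rm.run_vca(corrected.D, VcaOptions(rank=4, seed=3))
        for i, s in zip(res.options["indices"], res.S):
            np.testing.assert_array_equal(s, corrected.D[i])
        np.testing.assert_allclose(res.C.sum(axis=1), 1.0, atol=1e-6)

    def test_lowvar_water_found_at_rank_two(self):
        """A tiny-variance but spectrally distinct component is still a
        vertex, so the sequential projections pick it up."""
        hits = 0
        for seed in range(5):
            sc = rm.make_scene("lowvar_water", (30, 30), snr=30, seed=seed)
            res = rm.run_vca(sc.image.D, VcaOptions(rank=2, seed=seed))
            w = sc.S_true[sc.component_index("water")]
            r = np.abs(rm.endmember_correlations(w[None, :], res.S)).max()
            hits += r >= 0.95
        assert hits >= 4
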