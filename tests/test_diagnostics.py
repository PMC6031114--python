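"""Model statistics, endmember matching, rank scree and presentation rules."""

import numpy as np
import pytest

import ramanmix as rm
from ramanmix.diagnostics import (
    endmember_correlations,
    lack_of_fit,
    match_endmembers,
    normalize_to_band,
    r2_from_lof,
    rank_scree,
    render_abundance_map,
    variance_explained,
)


class TestLofR2:
    def test_perfect_reconstruction(self, rng):
        C = rng.random((6, 2))
        S = rng.random((2, 7))
        assert lack_of_fit(C @ S, C, S) == 0.0
        assert variance_explained(C @ S, C, S) == 100.0

    def test_proportional_residual_closed_form(self, rng):
        D = rng.random((8, 5)) + 0.1
        # model reproduces 0.9 * D exactly -> residual is 0.1 * D
        C = 0.9 * D
        S = np.eye(5)
        assert lack_of_fit(D, C, S) == pytest.approx(10.0, rel=1e-12)

    def test_brute_force_elementwise_oracle(self, rng):
        """Independent per-element summation reproduces both statistics."""
        D = rng.random((10, 6))
        C = rng.random((10, 3))
        S = rng.random((3, 6))
        M = C @ S
        ess = sum((D[i, j] - M[i, j]) ** 2 for i in range(10) for j in range(6))
        dss = sum(D[i, j] ** 2 for i in range(10) for j in range(6))
        assert lack_of_fit(D, C, S) == pytest.approx(
            100.0 * np.sqrt(ess / dss), rel=1e-12)
        assert variance_explained(D, C, S) == pytest.approx(
            100.0 * (1 - ess / dss), rel=1e-12)

    def test_residual_identity(self, rng):
        D = rng.random((12, 8)) + 0.05
        C = rng.random((12, 3))
        S = rng.random((3, 8))
        lof = lack_of_fit(D, C, S)
        assert variance_explained(D, C, S) == pytest.approx(
            r2_from_lof(lof), abs=1e-9)

    def test_extremes(self, rng):
        D = rng.random((5, 4)) + 0.1
        assert r2_from_lof(0.0) == 100.0
        # all-zero model: residual equals the data itself
        assert variance_explained(D, np.zeros((5, 2)), np.zeros((2, 4))) == \
            pytest.approx(0.0, abs=1e-12)

    def test_all_zero_reference_rejected(self):
        with pytest.raises(ValueError):
            lack_of_fit(np.zeros((3, 3)), np.zeros((3, 1)), np.zeros((1, 3)))


class TestCorrelations:
    def test_self_correlation_unit_diagonal(self, rng):
        S = rng.random((4, 30))
        R = endmember_correlations(S, S)
        np.testing.assert_allclose(np.diag(R), 1.0, atol=1e-12)
        np.testing.assert_allclose(R, R.T, atol=1e-12)

    def test_affine_invariance(self, rng):
        a = rng.random(25)
        R = endmember_correlations(a[None, :], (2.0 * a + 3.0)[None, :])
        assert R[0, 0] == pytest.approx(1.0, abs=1e-12)

    def test_disjoint_bands_nearly_uncorrelated(self, axis):
        from ramanmix.synth import BandSpec, ComponentSpectrum

        a = rm.render_component(ComponentSpectrum("a", [BandSpec(500, 20, 1.0)]), axis)
        b = rm.render_component(ComponentSpectrum("b", [BandSpec(1500, 20, 1.0)]), axis)
        assert abs(endmember_correlations(a[None], b[None])[0, 0]) < 0.2

    def test_constant_spectrum_flagged_zero(self, rng):
        with pytest.warns(UserWarning, match="constant"):
            R = endmember_correlations(np.ones((1, 10)), rng.random((2, 10)))
        np.testing.assert_array_equal(R, 0.0)


class TestMatching:
    def test_recovers_known_permutation(self, rng):
        S = rng.random((4, 40))
        sigma = [2, 0, 3, 1]
        perm, r, _ = match_endmembers(S, S[sigma])
        # perm[i] = position of S[i] inside S[sigma]
        assert [sigma[j] for j in perm] == [0, 1, 2, 3]
        assert min(r) == pytest.approx(1.0, abs=1e-12)

    def test_self_match_is_identity(self, rng):
        S = rng.random((5, 30))
        perm, _, _ = match_endmembers(S, S)
        assert perm == (0, 1, 2, 3, 4)

    def test_exhaustive_beats_greedy(self):
        """Fixture where row-wise greedy assignment is suboptimal."""
        # mean-zero orthonormal directions; spectra built to prescribed
        # pairwise correlations
        m = 8
        V = np.linalg.qr(np.random.default_rng(0).random((m, m)))[0]
        V = V - V.mean(axis=0, keepdims=True)
        V /= np.linalg.norm(V, axis=0)
        e = V.T[:4]
        R_target = np.array([  # greedy: 0.90+0.70+0.10=1.70 < optimal 1.75
            [0.90, 0.80, 0.00],
            [0.85, 0.70, 0.00],
            [0.00, 0.75, 0.10],
        ])
        S_a = e[:3]
        S_b = np.stack([
            sum(R_target[i, j] * e[i] for i in range(3))
            + np.sqrt(max(0.0, 1 - (R_target[:, j] ** 2).sum())) * e[3]
            for j in range(3)
        ])
        perm, r, _ = match_endmembers(S_a, S_b)
        # greedy oracle
        used, greedy = set(), 0.0
        R = endmember_correlations(S_a, S_b)
        for i in range(3):
            j = max((j for j in range(3) if j not in used), key=lambda j: R[i, j])
            used.add(j)
            greedy += R[i, j]
        assert sum(r) > greedy + 1e-6

    def test_rank_mismatch_rejected(self, rng):
        with pytest.raises(ValueError):
            match_endmembers(rng.random((3, 10)), rng.random((2, 10)))

    def test_cross_method_on_scene(self, spruce_scene):
        vca = rm.run_vca(spruce_scene.image.D, rm.VcaOptions(rank=4, seed=0))
        mcr = rm.mcr_als_fit(spruce_scene.image.D, rm.McrOptions(rank=4, seed=0))
        perm, r, abun_r = match_endmembers(vca, mcr)
        assert min(r) >= 0.9
        assert abun_r is not None


class TestRankScree:
    def test_exact_rank_counted(self, simplex_scene):
        s, rank = rank_scree(simplex_scene.image.D)
        assert (s[:3] > 1e-9 * s[0]).all() and s[3] < 1e-9 * s[0]
        assert rank == 3

    def test_noiseless_simplex_k4(self):
        sc = rm.make_scene("simplex", (10, 12), k=4, seed=5)
        _, rank = rank_scree(sc.image.D)
        assert rank == 4

    @pytest.mark.parametrize("seed", range(5))
    def test_pure_noise_suggests_at_most_one(self, seed):
        # map-like shape (pixels >> channels), as in real hyperspectral data
        D = np.abs(np.random.default_rng(seed).standard_normal((400, 60)))
        _, rank = rank_scree(D)
        assert rank <= 1


class TestPresentation:
    def test_min_max_scaling(self):
        C = np.array([[0.0], [5.0], [10.0]])
        img, flag = render_abundance_map(C, 0, (3, 1))
        np.testing.assert_allclose(img.ravel(), [0.0, 0.5, 1.0])
        assert not flag

    def test_constant_column_flagged(self):
        img, flag = render_abundance_map(np.ones((4, 1)), 0, (2, 2))
        assert flag and (img == 0).all()

    def test_water_map_bright_on_lumen(self, spruce_scene):
        res = rm.run_vca(spruce_scene.image.D, rm.VcaOptions(rank=4, seed=0))
        perm, r, _ = match_endmembers(spruce_scene.S_true, res.S)
        k = perm[spruce_scene.component_index("water")]
        img, _ = render_abundance_map(res.C, k, spruce_scene.image.grid_shape)
        lumen = spruce_scene.region_masks["lumen"]
        assert img[lumen].mean() > 0.9
        assert img[~lumen].mean() < 0.1

    def test_normalize_to_band(self, axis):
        s = np.ones(axis.n_channels)
        s[axis.index_of(1600)] = 4.0
        out = normalize_to_band(s, axis, 1600, window=20)
        assert out[axis.index_of(1600)] == pytest.approx(1.0)

    def test_normalization_preserves_ratios(self, axis, library):
        s = rm.render_component(library["lignin"], axis)
        out = normalize_to_band(s, axis, 1600, window=20)
        i, j = axis.index_of(1600), axis.index_of(1660)
        assert out[j] / out[i] == pytest.approx(s[j] / s[i], rel=1e-12)
        assert out[j] < 1.0  # 1600 is the dominant aromatic band

    def test_zero_normalizer_rejected(self, axis):
        with pytest.raises(ValueError):
            normalize_to_band(np.zeros(axis.n_channels), axis, 1600)
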