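import numpy as np
import pytest

import loki
from loki import align as al
from loki import encoder as enc


def reference_em_step(X, T, Y, beta, lam, w, sigma2):
    """Straight-from-the-definitions EM step of coordinate-only non-rigid CPD.

    Independent loop implementation: Gaussian posteriors with a uniform
    outlier term, regularized linear solve for W, and the trace-form variance
    update. Serves as the oracle for the vectorized implementation.
    """
    M, D = T.shape
    N = X.shape[0]
    G = np.zeros((M, M))
    for i in range(M):
        for j in range(M):
            G[i, j] = np.exp(-np.sum((Y[i] - Y[j]) ** 2) / (2 * beta**2))
    P = np.zeros((M, N))
    for n in range(N):
        denom = w / (1 - w) * (2 * np.pi * sigma2) ** (D / 2) * M / N
        for k in range(M):
            denom += np.exp(-np.sum((X[n] - T[k]) ** 2) / (2 * sigma2))
        for m in range(M):
            P[m, n] = np.exp(-np.sum((X[n] - T[m]) ** 2) / (2 * sigma2)) / denom
    p1 = P.sum(axis=1)
    A = G + lam * sigma2 * np.diag(1.0 / p1)
    rhs = np.diag(1.0 / p1) @ P @ X[:, :2] - Y[:, :2]
    W = np.linalg.solve(A, rhs)
    T_new = Y.copy()
    T_new[:, :2] = Y[:, :2] + G @ W
    Np = p1.sum()
    pt1 = P.sum(axis=0)
    s2 = (
        np.trace(X.T @ np.diag(pt1) @ X)
        - 2 * np.trace((P @ X).T @ T_new)
        + np.trace(T_new.T @ np.diag(p1) @ T_new)
    ) / (Np * D)
    return P, W, T_new, s2


class TestAugmentPoints:
    def make_emb(self, vectors):
        v = np.asarray(vectors, dtype=float)
        v = v / np.linalg.norm(v, axis=1, keepdims=True)
        return enc.EmbeddingMatrix(v, np.arange(len(v)).astype(object), "text")

    def test_gamma_zero_reduces_to_normalized_coords(self, rng):
        coords = rng.uniform(0, 100, (10, 2))
        emb = self.make_emb(rng.standard_normal((10, 8)))
        aug = al.augment_points(coords, emb, gamma=0.0)
        center = coords.mean(axis=0)
        scale = np.abs(coords - center).max()
        np.testing.assert_allclose(aug[:, :2], (coords - center) / scale)
        np.testing.assert_array_equal(aug[:, 2:], 0.0)

    def test_identical_embeddings_zero_pc_columns(self, rng):
        coords = rng.uniform(0, 100, (6, 2))
        emb = self.make_emb(np.tile(rng.standard_normal(8), (6, 1)))
        aug = al.augment_points(coords, emb, gamma=1.0)
        np.testing.assert_array_equal(aug[:, 2:], 0.0)

    def test_pc_columns_scaled_to_coordinate_std(self, rng):
        coords = rng.uniform(0, 100, (50, 2))
        emb = self.make_emb(rng.standard_normal((50, 16)))
        aug = al.augment_points(coords, emb, gamma=1.0)
        np.testing.assert_allclose(aug[:, 2].std(), aug[:, :2].std(), atol=1e-9)
        np.testing.assert_allclose(aug[:, 3].std(), aug[:, :2].std(), atol=1e-9)

    def test_too_few_points_rejected(self, rng):
        with pytest.raises(ValueError, match="3"):
            al.augment_points(np.zeros((2, 2)), self.make_emb(rng.standard_normal((2, 4))), 1.0)


class TestCPDOracle:
    @pytest.mark.parametrize("m,n,seed", [(4, 4, 0), (7, 10, 1), (10, 8, 2)])
    def test_one_em_step_matches_reference(self, m, n, seed):
        rng = np.random.default_rng(seed)
        Y = rng.uniform(-1, 1, (m, 2))
        X = rng.uniform(-1, 1, (n, 2))
        params = al.CPDParams(beta=1.5, lam=2.0, w=0.0, clip_W=False)
        sigma2 = float(((X[None] - Y[:, None]) ** 2).sum()) / (2 * m * n)
        G = np.exp(-((Y[:, None] - Y[None]) ** 2).sum(axis=2) / (2 * params.beta**2))
        P, W, T, s2 = al.cpd_em_step(X, Y.copy(), Y, G, sigma2, params)
        P0, W0, T0, s20 = reference_em_step(X, Y.copy(), Y, params.beta, params.lam, 0.0, sigma2)
        np.testing.assert_allclose(P, P0, atol=1e-10)
        np.testing.assert_allclose(W, W0, atol=1e-10)
        np.testing.assert_allclose(T, T0, atol=1e-10)
        assert abs(s2 - s20) < 1e-10

    def test_outlier_term_matches_reference(self):
        rng = np.random.default_rng(3)
        Y = rng.uniform(-1, 1, (5, 2))
        X = rng.uniform(-1, 1, (6, 2))
        params = al.CPDParams(beta=2.0, lam=1.0, w=0.3, clip_W=False)
        sigma2 = 0.5
        G = np.exp(-((Y[:, None] - Y[None]) ** 2).sum(axis=2) / (2 * params.beta**2))
        P, W, T, s2 = al.cpd_em_step(X, Y.copy(), Y, G, sigma2, params)
        P0, W0, T0, s20 = reference_em_step(X, Y.copy(), Y, 2.0, 1.0, 0.3, sigma2)
        np.testing.assert_allclose(P, P0, atol=1e-10)
        np.testing.assert_allclose(W, W0, atol=1e-10)
        assert abs(s2 - s20) < 1e-10

    def test_sigma2_stays_nonnegative(self, rng):
        Y = rng.uniform(-1, 1, (20, 2))
        X = rng.uniform(-1, 1, (25, 2))
        params = al.CPDParams(w=0.1, clip_W=False, max_iter=40)
        G = np.exp(-((Y[:, None] - Y[None]) ** 2).sum(axis=2) / (2 * params.beta**2))
        sigma2 = float(((X[None] - Y[:, None]) ** 2).sum()) / (2 * len(Y) * len(X))
        T = Y.copy()
        for _ in range(40):
            _, _, T, sigma2 = al.cpd_em_step(X, T, Y, G, sigma2, params)
            assert sigma2 >= 0


class TestCPDAlign:
    def test_identity_case_near_zero_displacement(self, rng):
        pts = rng.uniform(0, 100, (50, 2))
        res = al.cpd_align(pts, pts, al.CPDParams(w=0.0))
        diam = np.ptp(pts, axis=0).max()
        assert np.linalg.norm(res.aligned_coords - pts, axis=1).mean() < 1e-6 * diam

    def test_known_rotation_translation_recovery(self, rng):
        src = rng.uniform(0, 100, (200, 2))
        theta = np.radians(10)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        tgt = src @ R.T + [15.0, -8.0]
        pre = np.linalg.norm(src - tgt, axis=1).mean()
        res = al.cpd_align(src, tgt, al.CPDParams(w=0.0, gamma=0.0))
        from scipy.spatial import cKDTree

        post = cKDTree(tgt).query(res.aligned_coords)[0].mean()
        assert post < 0.05 * pre


class TestRigidRegularize:
    def test_recovers_planted_rotation(self, rng):
        pts = rng.uniform(0, 10, (30, 2))
        theta = np.radians(30)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pts @ R.T + [1.0, 2.0]
        Rhat, that, rigid = al.rigid_regularize(pts, moved)
        assert np.degrees(np.arctan2(Rhat[1, 0], Rhat[0, 0])) == pytest.approx(30.0, abs=1e-6)
        np.testing.assert_allclose(rigid, moved, atol=1e-9)

    def test_identity_when_unmoved(self, rng):
        pts = rng.uniform(0, 10, (10, 2))
        R, t, rigid = al.rigid_regularize(pts, pts)
        np.testing.assert_allclose(R, np.eye(2), atol=1e-9)
        np.testing.assert_allclose(t, 0.0, atol=1e-9)

    def test_reflection_projected_to_proper_rotation(self, rng):
        pts = rng.uniform(0, 10, (20, 2))
        reflected = pts * [1.0, -1.0]
        R, _, _ = al.rigid_regularize(pts, reflected)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)

    def test_collinear_input_falls_back_to_identity(self):
        pts = np.column_stack([np.arange(5.0), np.zeros(5)])
        R, _, _ = al.rigid_regularize(pts, pts + [0.0, 1.0])
        np.testing.assert_allclose(R, np.eye(2))

    def test_exact_when_displacement_is_rigid(self, rng):
        pts = rng.uniform(0, 100, (40, 2))
        theta = np.radians(-17.0)
        R = np.array([[np.cos(theta), -np.sin(theta)], [np.sin(theta), np.cos(theta)]])
        moved = pts @ R.T + [3.0, 4.0]
        _, _, rigid = al.rigid_regularize(pts, moved)
        assert np.abs(rigid - moved).max() < 1e-9


class TestAlignSlides:
    def test_identity_alignment_near_zero(self, medium_slide, hash_backend):
        slide, _ = medium_slide
        res = al.align_slides(slide, slide, hash_backend, al.CPDParams(), mode="st_to_st")
        assert res.displacement_per_spot.mean() < 0.02 * slide.pitch_um

    def test_recovery_from_rotation_and_jitter(self, medium_slide, hash_backend):
        slide, _ = medium_slide
        pert, truth = loki.perturb_alignment(slide, 0.05, 5.0, 10.0, seed=5)
        pre = np.linalg.norm(pert.coords - truth["true_coords"], axis=1).mean()
        for mode in ("st_to_st", "image_to_st"):
            res = al.align_slides(pert, slide, hash_backend, al.CPDParams(), mode=mode)
            post = np.linalg.norm(res.aligned_coords - truth["true_coords"], axis=1).mean()
            assert post < 0.10 * pre, mode

    def test_image_mode_without_patches_rejected(self, medium_slide, hash_backend):
        slide, _ = medium_slide
        from dataclasses import replace

        bare = replace(slide, patches=None)
        with pytest.raises(ValueError, match="patch"):
            al.align_slides(bare, slide, hash_backend, mode="image_to_st")

    def test_error_monotone_in_coordinate_noise(self, hash_backend):
        from scipy.stats import spearmanr

        levels = [2.0, 8.0, 25.0]
        medians = []
        for sd in levels:
            errs = []
            for seed in range(10):
                slide, _ = loki.make_slide(loki.SynthConfig(n_spots=120, n_genes=120, n_types=4, seed=seed))
                pert, truth = loki.perturb_alignment(slide, 0.05, sd, 10.0, seed=seed + 50)
                res = al.align_slides(pert, slide, hash_backend, al.CPDParams(), mode="st_to_st")
                errs.append(np.linalg.norm(res.aligned_coords - truth["true_coords"], axis=1).mean())
            medians.append(np.median(errs))
        rho = spearmanr(levels, medians).statistic
        assert rho >= 0.8


class TestEvaluateAlignment:
    def test_identity_alignment_gives_median_pcc_one(self, medium_slide):
        slide, _ = medium_slide
        report = al.evaluate_alignment(slide.coords, slide, slide, n_hvg=20)
        assert report["median_pcc"] == pytest.approx(1.0)
        assert report["median_tau"] == pytest.approx(1.0)

    def test_shuffled_expression_gives_near_zero_pcc(self, medium_slide, rng):
        slide, _ = medium_slide
        from dataclasses import replace

        shuffled = replace(slide, counts=slide.counts[rng.permutation(slide.n_spots)])
        report = al.evaluate_alignment(slide.coords, shuffled, slide, n_hvg=20)
        assert abs(report["median_pcc"]) < 0.2

    def test_zero_match_radius_raises(self, medium_slide):
        slide, _ = medium_slide
        with pytest.raises(ValueError, match="match"):
            al.evaluate_alignment(slide.coords + 1.0, slide, slide, match_radius=0.0)
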