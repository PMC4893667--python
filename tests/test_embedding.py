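import numpy as np
import pytest
import scipy.linalg as sla

from osessl import (
    LabelAssignment,
    compute_similarity,
    construct_ose_ssl,
    graph_embed,
    lpp_embed,
    median_sigma,
    pca_embed,
    project_linear,
    silhouette_index,
    supervise_similarity,
)
from osessl.affinity import SimilarityMatrix, from_values
from osessl.embedding import UNKNOWN, ZERO_EIG_TOL, label_refinement

from .conftest import random_dissimilarity


def brute_force_embed(W, d):
    """Dense full-spectrum oracle for the generalized eigenproblem."""
    deg = W.values.sum(axis=1)
    L = np.diag(deg) - W.values
    vals, vecs = sla.eigh(L, np.diag(deg))
    keep = np.flatnonzero(vals > ZERO_EIG_TOL)[:d]
    return vals[keep], vecs[:, keep]


def align_signs(reference, candidate):
    signs = np.sign(np.einsum("ik,ik->k", reference, candidate))
    signs[signs == 0] = 1.0
    return candidate * signs


class TestGraphEmbed:
    def test_two_point_hand_solution(self):
        # W = [[1, w], [w, 1]]: nontrivial eigenpair lambda = 2w/(1+w),
        # y proportional to (1, -1) with unit D-norm
        w = 0.4
        W = SimilarityMatrix(values=np.array([[1.0, w], [w, 1.0]]), sigma=1.0)
        space = graph_embed(W, 1)
        assert space.eigenvalues[0] == pytest.approx(2 * w / (1 + w), abs=1e-12)
        expected = np.array([1.0, -1.0]) / np.sqrt(2 * (1 + w))
        np.testing.assert_allclose(space.coordinates[:, 0], expected, atol=1e-12)

    def test_near_duplicate_points_embed_together(self):
        # images 0 and 1 identical, image 2 far away
        A = from_values([[0, 0, 10], [0, 0, 10], [10, 10, 0]])
        space = graph_embed(compute_similarity(A, sigma=2.0), 1)
        y = space.coordinates[:, 0]
        assert abs(y[0] - y[1]) < 1e-8
        assert abs(y[2] - y[0]) > 10 * abs(y[0] - y[1] + 1e-30)

    def test_constant_vector_excluded(self, rng):
        A = random_dissimilarity(rng, 9, scale=4)
        space = graph_embed(compute_similarity(A, sigma=1.0), 3)
        assert np.all(space.eigenvalues > ZERO_EIG_TOL)
        # no returned coordinate column is the constant vector
        for k in range(space.d):
            assert np.ptp(space.coordinates[:, k]) > 1e-6

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(25):
            n = int(rng.integers(4, 21))
            A = random_dissimilarity(rng, n, scale=5)
            W = compute_similarity(A, float(rng.uniform(0.5, 3.0)))
            d = int(rng.integers(1, min(4, n - 1)))
            space = graph_embed(W, d)
            vals, vecs = brute_force_embed(W, d)
            np.testing.assert_allclose(space.eigenvalues, vals, atol=1e-8)
            aligned = align_signs(space.coordinates, vecs)
            np.testing.assert_allclose(space.coordinates, aligned, atol=1e-8)

    def test_eigen_residual_and_d_orthogonality(self, rng):
        A = random_dissimilarity(rng, 15, scale=3)
        W = compute_similarity(A, 1.5)
        space = graph_embed(W, 4)
        deg = W.values.sum(axis=1)
        L = np.diag(deg) - W.values
        for k in range(space.d):
            y = space.coordinates[:, k]
            lam = space.eigenvalues[k]
            resid = np.linalg.norm(L @ y - lam * deg * y)
            assert resid <= 1e-8 * np.linalg.norm(deg * y)
        gram = space.coordinates.T @ (deg[:, None] * space.coordinates)
        np.testing.assert_allclose(gram, np.eye(space.d), atol=1e-8)

    def test_eigenvalues_ascending(self, rng):
        A = random_dissimilarity(rng, 12, scale=2)
        space = graph_embed(compute_similarity(A, 1.0), 5)
        assert np.all(np.diff(space.eigenvalues) >= 0)

    def test_d_too_large_rejected(self, rng):
        A = random_dissimilarity(rng, 5)
        with pytest.raises(ValueError, match="nonzero eigenpairs"):
            graph_embed(compute_similarity(A, 1.0), 5)

    def test_disconnected_graph_warns_and_excludes_components(self):
        # two far-apart pairs: affinity between pairs underflows to ~0
        A = from_values(
            [
                [0, 1, 4000, 4000],
                [1, 0, 4000, 4000],
                [4000, 4000, 0, 1],
                [4000, 4000, 1, 0],
            ]
        )
        W = compute_similarity(A, sigma=1.0)
        with pytest.warns(RuntimeWarning, match="disconnected"):
            space = graph_embed(W, 2)
        assert np.all(space.eigenvalues > ZERO_EIG_TOL)


class TestSuperviseSimilarity:
    def test_no_labels_leaves_w_unchanged(self, rng):
        A = random_dissimilarity(rng, 8)
        W = compute_similarity(A, 1.0)
        Wr = supervise_similarity(W, LabelAssignment.all_unknown(8))
        np.testing.assert_array_equal(Wr.values, W.values)

    def test_multiplicative_form_values(self):
        gamma = np.array([0.5, 0.5, 0.0])
        same = np.array([True, False, True])
        unknown = np.array([False, False, False])
        out = label_refinement(gamma, same, unknown)
        np.testing.assert_allclose(out, [0.75, 0.25, 0.0])

    def test_direction_per_pair(self, rng):
        """Refined affinity is boosted iff same class, damped iff
        different, unchanged iff either label is unknown."""
        for _ in range(20):
            n = int(rng.integers(4, 15))
            A = random_dissimilarity(rng, n, scale=3)
            W = compute_similarity(A, 1.0)
            labels = rng.choice([UNKNOWN, 1, 2, 3], size=n)
            if len(set(labels[labels != UNKNOWN])) < 2:
                continue
            Wr = supervise_similarity(W, LabelAssignment(labels=labels, Z=3))
            for i in range(n):
                for j in range(i + 1, n):
                    g, gr = W.values[i, j], Wr.values[i, j]
                    if labels[i] == UNKNOWN or labels[j] == UNKNOWN:
                        assert gr == g
                    elif labels[i] == labels[j]:
                        assert gr > g
                    else:
                        assert gr < g

    def test_diagonal_unchanged_and_symmetric(self, rng):
        A = random_dissimilarity(rng, 6)
        W = compute_similarity(A, 1.0)
        labels = np.array([1, 1, 2, 2, UNKNOWN, UNKNOWN])
        Wr = supervise_similarity(W, LabelAssignment(labels=labels, Z=2))
        np.testing.assert_array_equal(np.diag(Wr.values), np.diag(W.values))
        np.testing.assert_array_equal(Wr.values, Wr.values.T)

    def test_single_known_class_rejected(self, rng):
        A = random_dissimilarity(rng, 4)
        W = compute_similarity(A, 1.0)
        labels = np.array([1, 1, UNKNOWN, UNKNOWN])
        with pytest.raises(ValueError, match="two distinct"):
            supervise_similarity(W, LabelAssignment(labels=labels, Z=1))

    def test_supervision_separates_swiss_roll_classes(self, small_roll):
        """Full supervision (m = 1) yields a 2-D embedding whose classes
        are better separated (higher silhouette) than without labels."""
        sigma = median_sigma(small_roll.dissimilarity)
        truth = LabelAssignment(labels=small_roll.labels)
        unsup = construct_ose_ssl(
            small_roll.dissimilarity, LabelAssignment.all_unknown(small_roll.n), sigma, 2
        )
        sup = construct_ose_ssl(small_roll.dissimilarity, truth, sigma, 2)
        assert (
            silhouette_index(sup.coordinates, truth).overall
            > silhouette_index(unsup.coordinates, truth).overall
        )


class TestPcaEmbed:
    def test_identical_rows_project_identically(self):
        A = from_values([[0, 1, 1], [1, 0, 2], [1, 2, 0]])
        values = A.values.copy()
        # make rows 0 and 1 identical in feature space is impossible for a
        # valid dissimilarity matrix; instead check zero-variance directly
        proj = pca_embed(A, 1)
        recon = project_linear(proj, values[0])
        np.testing.assert_allclose(recon, proj.coordinates[0], atol=1e-12)

    def test_matches_covariance_eigendecomposition(self, rng):
        A = random_dissimilarity(rng, 4, scale=5)
        proj = pca_embed(A, 2)
        X = A.values - A.values.mean(axis=0)
        cov_vals, cov_vecs = np.linalg.eigh(X.T @ X)
        top = cov_vecs[:, np.argsort(cov_vals)[::-1][:2]]
        # compare projected coordinates up to per-column sign
        expected = X @ top
        for k in range(2):
            dots = expected[:, k] @ proj.coordinates[:, k]
            np.testing.assert_allclose(
                proj.coordinates[:, k], np.sign(dots) * expected[:, k], atol=1e-8
            )

    def test_basis_orthonormal(self, rng):
        A = random_dissimilarity(rng, 10, scale=3)
        proj = pca_embed(A, 4)
        np.testing.assert_allclose(proj.basis.T @ proj.basis, np.eye(4), atol=1e-10)

    def test_d_beyond_rank_rejected(self, rng):
        A = random_dissimilarity(rng, 5)
        with pytest.raises(ValueError, match="rank"):
            pca_embed(A, 5)


class TestLppEmbed:
    def test_separates_two_blobs_by_sign(self, rng):
        left = rng.normal(-8, 0.5, size=(12, 3))
        right = rng.normal(8, 0.5, size=(12, 3))
        from scipy.spatial.distance import cdist

        points = np.vstack([left, right])
        A = from_values(cdist(points, points))
        W = compute_similarity(A, median_sigma(A))
        proj = lpp_embed(A, W, 1)
        signs = np.sign(proj.coordinates[:, 0])
        assert len(set(signs[:12])) == 1 and len(set(signs[12:])) == 1
        assert signs[0] != signs[12]

    def test_database_row_projection_consistency(self, rng):
        A = random_dissimilarity(rng, 9, scale=2)
        W = compute_similarity(A, 1.0)
        proj = lpp_embed(A, W, 2)
        for i in (0, 4, 8):
            np.testing.assert_allclose(
                project_linear(proj, A.values[i]), proj.coordinates[i], atol=1e-10
            )

    def test_singular_denominator_regularized(self, rng, caplog):
        # centering makes X^T D X rank deficient, so the ridge path runs
        import logging

        A = random_dissimilarity(rng, 8, scale=2)
        W = compute_similarity(A, 1.0)
        with caplog.at_level(logging.INFO, logger="osessl.embedding"):
            proj = lpp_embed(A, W, 1)
        assert proj.coordinates.shape == (8, 1)
        assert any("ridge" in record.message for record in caplog.records)


class TestProjectLinear:
    def test_center_maps_to_origin(self, rng):
        A = random_dissimilarity(rng, 6)
        proj = pca_embed(A, 2)
        np.testing.assert_allclose(project_linear(proj, proj.center), 0.0, atol=1e-12)

    def test_length_mismatch_rejected(self, rng):
        A = random_dissimilarity(rng, 6)
        proj = pca_embed(A, 2)
        with pytest.raises(ValueError):
            project_linear(proj, np.zeros(5))
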