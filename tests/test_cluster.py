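"""Dissimilarities, PAM, k-means and silhouette scoring."""

import itertools

import numpy as np
import pytest
from scipy.stats import spearmanr
from sklearn.metrics import adjusted_rand_score

from omicsfuse.cluster import (
    ClusterSolution,
    DissimilarityMatrix,
    euclidean_dissimilarity,
    kmeans,
    pam,
    silhouette,
    spearman_dissimilarity,
    sweep,
)


def brute_silhouette(d, labels):
    """Literal double-loop evaluation of s(i) = (b-a)/max(a,b)."""
    labels = np.asarray(labels)
    n = len(labels)
    out = np.zeros(n)
    for i in range(n):
        own = (labels == labels[i])
        if own.sum() == 1:
            out[i] = 0.0
            continue
        a = d[i][own & (np.arange(n) != i)].mean()
        b = min(
            d[i][labels == c].mean() for c in np.unique(labels) if c != labels[i]
        )
        out[i] = (b - a) / max(a, b)
    return out


def random_dissimilarity(rng, n):
    m = rng.random((n, n))
    m = (m + m.T) / 2
    np.fill_diagonal(m, 0.0)
    return m


class TestSpearmanDistance:
    def test_identical_ranking_gives_zero(self):
        d = spearman_dissimilarity(
            np.array([[1.0, 2, 3, 4], [10.0, 20, 30, 40]])
        )
        assert d.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_reversed_ranking_gives_two(self):
        d = spearman_dissimilarity(np.array([[1.0, 2, 3, 4], [4.0, 3, 2, 1]]))
        assert d.values[0, 1] == pytest.approx(2.0, abs=1e-12)

    def test_tied_ranks_match_reference_formula(self):
        x = np.array([1.0, 2.0, 2.0, 4.0])
        y = np.array([3.0, 1.0, 4.0, 2.0])
        d = spearman_dissimilarity(np.vstack([x, y]))
        rho_ref = spearmanr(x, y).statistic
        assert abs(d.values[0, 1] - (1 - rho_ref)) < 1e-12

    def test_constant_vector_names_sample(self):
        emb = np.array([[1.0, 2.0, 3.0], [5.0, 5.0, 5.0]])
        with pytest.raises(ValueError, match="sample index 1"):
            spearman_dissimilarity(emb)

    def test_needs_two_dimensions(self):
        with pytest.raises(ValueError, match="2 latent"):
            spearman_dissimilarity(np.ones((4, 1)))


class TestPAM:
    def test_two_blobs_match_exhaustive_optimum(self):
        rng = np.random.default_rng(0)
        pts = np.vstack([rng.normal(0, 0.2, (4, 2)), rng.normal(5, 0.2, (4, 2))])
        d = euclidean_dissimilarity(pts)
        sol = pam(d, 2)
        best = min(
            d.values[list(pair)].min(axis=0).sum()
            for pair in itertools.combinations(range(8), 2)
        )
        assert sol.cost == pytest.approx(best, abs=1e-12)
        assert adjusted_rand_score([0] * 4 + [1] * 4, sol.labels) == 1.0

    def test_k1_returns_column_sum_minimiser(self):
        rng = np.random.default_rng(1)
        d = DissimilarityMatrix(random_dissimilarity(rng, 9), "euclidean")
        sol = pam(d, 1)
        assert sol.medoids[0] == int(np.argmin(d.values.sum(axis=0)))
        assert sol.cost == pytest.approx(d.values.sum(axis=0).min())

    def test_equidistant_points_cost(self):
        n = 6
        m = np.ones((n, n)) - np.eye(n)
        sol = pam(DissimilarityMatrix(m, "euclidean"), 2)
        assert sol.cost == pytest.approx(n - 2)  # every non-medoid costs 1

    def test_k_out_of_range(self):
        d = DissimilarityMatrix(np.zeros((4, 4)), "euclidean")
        with pytest.raises(ValueError, match="out of range"):
            pam(d, 4)


class TestKMeans:
    def test_separated_blobs_recovered(self, blob_embedding):
        emb, labels = blob_embedding
        sol = kmeans(emb, 3, seed=0)
        assert adjusted_rand_score(labels, sol.labels) == 1.0

    def test_k_equals_n_gives_zero_inertia(self):
        pts = np.random.default_rng(2).normal(size=(7, 3))
        sol = kmeans(pts, 7, seed=0)
        assert sol.cost == pytest.approx(0.0, abs=1e-20)

    def test_duplicate_rows_share_labels(self):
        rng = np.random.default_rng(3)
        base = rng.normal(size=(5, 4)) * 3
        pts = np.vstack([base, base])
        sol = kmeans(pts, 5, seed=0)
        np.testing.assert_array_equal(sol.labels[:5], sol.labels[5:])


class TestSilhouette:
    def test_hand_worked_two_pair_example(self):
        d = np.full((4, 4), 10.0)
        np.fill_diagonal(d, 0.0)
        d[0, 1] = d[1, 0] = 0.1
        d[2, 3] = d[3, 2] = 0.1
        values, mean = silhouette(
            DissimilarityMatrix(d, "euclidean"), np.array([1, 1, 2, 2])
        )
        np.testing.assert_allclose(values, [0.99] * 4)
        assert mean == pytest.approx(0.99)

    def test_matches_brute_force_on_random_instances(self):
        rng = np.random.default_rng(4)
        for _ in range(5):
            d = random_dissimilarity(rng, 20)
            labels = rng.integers(0, 3, 20)
            labels[:3] = [0, 1, 2]  # keep clusters non-empty
            values, _ = silhouette(DissimilarityMatrix(d, "euclidean"), labels)
            np.testing.assert_allclose(values, brute_silhouette(d, labels),
                                       atol=1e-12)

    def test_all_singletons_score_zero(self):
        rng = np.random.default_rng(5)
        d = DissimilarityMatrix(random_dissimilarity(rng, 5), "euclidean")
        values, mean = silhouette(d, np.arange(5))
        assert np.all(values == 0.0) and mean == 0.0

    def test_invariant_to_label_renaming(self):
        rng = np.random.default_rng(6)
        d = DissimilarityMatrix(random_dissimilarity(rng, 12), "euclidean")
        labels = rng.integers(0, 3, 12)
        labels[:3] = [0, 1, 2]
        v1, _ = silhouette(d, labels)
        v2, _ = silhouette(d, (labels + 1) % 3)
        np.testing.assert_allclose(v1, v2, atol=1e-12)

    def test_single_cluster_rejected(self):
        d = DissimilarityMatrix(np.zeros((3, 3)), "euclidean")
        with pytest.raises(ValueError, match="2 clusters"):
            silhouette(d, np.zeros(3, dtype=int))


class TestSweep:
    def test_default_grid_has_eight_solutions(self, blob_embedding):
        emb, _ = blob_embedding
        sols = sweep(emb, seed=0)
        assert len(sols) == 8
        assert {(s.algorithm, s.metric) for s in sols} == {
            ("pam", "spearman"), ("kmeans", "euclidean"),
        }

    def test_restricted_k_range(self, blob_embedding):
        emb, _ = blob_embedding
        assert len(sweep(emb, k_range=[3], seed=0)) == 2

    def test_planted_k_maximises_silhouette_for_both_pairings(
        self, blob_embedding
    ):
        emb, _ = blob_embedding
        sols = sweep(emb, seed=0)
        for algorithm in ("pam", "kmeans"):
            arm = [s for s in sols if s.algorithm == algorithm]
            best = max(arm, key=lambda s: s.mean_silhouette)
            assert best.k == 3

    def test_silhouette_uses_clustering_metric(self, blob_embedding):
        emb, _ = blob_embedding
        sols = sweep(emb, k_range=[3], seed=0)
        for s in sols:
            d = (
                spearman_dissimilarity(emb)
                if s.metric == "spearman"
                else euclidean_dissimilarity(emb)
            )
            _, mean = silhouette(d, s.labels)
            assert s.mean_silhouette == pytest.approx(mean, abs=1e-12)


def test_cluster_solution_requires_k_nonempty_clusters():
    with pytest.raises(ValueError, match="non-empty"):
        ClusterSolution(
            labels=np.array([0, 0, 0]), k=2, algorithm="pam",
            metric="euclidean", cost=0.0,
        )
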