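import numpy as np
import pytest
from sklearn.metrics import adjusted_rand_score

from adsubtype.cluster import (ClusteringConfig, ConsensusError,
                               GammaSearchError, canonicalize_labels,
                               consensus_cluster, default_gamma_grid,
                               gamma_search, louvain, modularity,
                               similarity_matrix)


def _hand_correlation(u, v):
    """Independent covariance-formula oracle."""
    n = len(u)
    su, sv = u.sum(), v.sum()
    cov = (u * v).sum() / n - su * sv / n ** 2
    vu = (u * u).sum() / n - (su / n) ** 2
    vv = (v * v).sum() / n - (sv / n) ** 2
    return cov / np.sqrt(vu * vv)


class TestSimilarityMatrix:
    def test_identical_vectors(self):
        z = np.vstack([np.arange(10.0)] * 3)
        S = similarity_matrix(z + np.zeros((3, 1)))
        assert S[0, 1] == pytest.approx(1.0)

    def test_negation(self):
        base = np.arange(10.0)
        z = np.vstack([base, -base, base + 1])
        S = similarity_matrix(z)
        assert S[0, 1] == pytest.approx(-1.0)

    def test_against_hand_rolled_oracle(self):
        rng = np.random.default_rng(5)
        z = rng.normal(size=(5, 100))
        S = similarity_matrix(z)
        for i in range(5):
            for j in range(i + 1, 5):
                assert S[i, j] == pytest.approx(_hand_correlation(z[i], z[j]),
                                                abs=1e-12)

    def test_zero_variance_row_named(self):
        z = np.vstack([np.ones(10), np.arange(10.0), np.arange(10.0) ** 2])
        with pytest.raises(ValueError, match="subjA"):
            similarity_matrix(z, subject_ids=["subjA", "b", "c"])

    def test_symmetry_and_range(self, small_zscores):
        S = similarity_matrix(small_zscores["tau"].to_numpy())
        assert np.allclose(S, S.T, atol=1e-12)
        off = S[~np.eye(len(S), dtype=bool)]
        assert off.min() >= -1.0 and off.max() <= 1.0


class TestModularity:
    def test_two_triangles_component_partition(self, two_triangles):
        q = modularity(two_triangles, np.array([1, 1, 1, 2, 2, 2]), gamma=1.0)
        assert q == pytest.approx(0.5)  # 2 * (0.5 - 0.25)

    def test_single_community_zero(self, two_triangles):
        assert modularity(two_triangles, np.ones(6), 1.0) == pytest.approx(0.0)

    def test_all_singletons(self, two_triangles):
        q = modularity(two_triangles, np.arange(6), 1.0)
        assert q == pytest.approx(-1.0 / 6.0)  # -6 * (2/12)^2

    def test_zero_weight_error(self):
        with pytest.raises(ValueError, match="zero"):
            modularity(np.zeros((4, 4)), np.arange(4), 1.0)

    def test_gamma_scales_null_term(self, two_triangles):
        lab = np.array([1, 1, 1, 2, 2, 2])
        q1 = modularity(two_triangles, lab, 1.0)
        q2 = modularity(two_triangles, lab, 2.0)
        assert q2 == pytest.approx(q1 - 0.5)  # extra gamma * sum(d_c/2m)^2 = 0.5


class TestLouvain:
    def test_two_cliques_any_seed(self, two_triangles):
        for seed in range(5):
            res = louvain(two_triangles, 1.0, seed=seed)
            assert adjusted_rand_score(res.labels, [0, 0, 0, 1, 1, 1]) == 1.0

    def test_planted_blocks_recovered(self, block_similarity):
        S, truth = block_similarity
        res = louvain(S, 1.0, seed=3)
        assert adjusted_rand_score(res.labels, truth) == 1.0

    def test_q_equals_modularity_of_labels(self, block_similarity):
        S, _ = block_similarity
        res = louvain(S, 1.2, seed=1)
        assert res.modularity == pytest.approx(
            modularity(S, res.labels, 1.2), abs=1e-12)

    def test_higher_gamma_no_fewer_communities(self):
        rng = np.random.default_rng(8)
        labels = np.repeat([0, 1], 20)
        S = np.where(labels[:, None] == labels[None, :], 0.4, 0.2)
        S = (S + rng.normal(0, 0.05, S.shape))
        S = (S + S.T) / 2
        np.fill_diagonal(S, 1.0)
        for seed in range(3):
            k_low = louvain(S, 1.0, seed=seed).labels.max()
            k_high = louvain(S, 10.0, seed=seed).labels.max()
            assert k_high >= k_low

    def test_labels_canonical_from_one(self, block_similarity):
        S, _ = block_similarity
        labels = louvain(S, 1.0, seed=0).labels
        assert labels.min() == 1
        sizes = np.bincount(labels)[1:]
        assert list(sizes) == sorted(sizes, reverse=True)


class TestConsensus:
    def test_two_cliques_single_round_binary(self, two_triangles):
        cp = consensus_cluster(two_triangles,
                               ClusteringConfig(gamma=1.0, n_iterations=20,
                                                seed=0))
        assert cp.rounds == 1
        off = cp.coassignment[~np.eye(6, dtype=bool)]
        assert set(np.round(off, 12)) <= {0.0, 1.0}
        assert adjusted_rand_score(cp.labels, [0, 0, 0, 1, 1, 1]) == 1.0

    def test_planted_blocks_across_master_seeds(self, block_similarity):
        S, truth = block_similarity
        for seed in range(10):
            cp = consensus_cluster(S, ClusteringConfig(gamma=1.0,
                                                       n_iterations=50,
                                                       seed=seed))
            assert adjusted_rand_score(cp.labels, truth) == 1.0

    def test_pure_noise_still_returns_labeling(self):
        rng = np.random.default_rng(12)
        X = rng.normal(size=(30, 40))
        S = np.corrcoef(X)
        cp = consensus_cluster(S, ClusteringConfig(gamma=1.2, n_iterations=50,
                                                   seed=1))
        assert cp.labels.shape == (30,)
        assert cp.labels.min() == 1

    def test_determinism(self, block_similarity):
        S, _ = block_similarity
        cfg = ClusteringConfig(gamma=1.0, n_iterations=30, seed=7)
        a = consensus_cluster(S, cfg)
        b = consensus_cluster(S, cfg)
        assert np.array_equal(a.labels, b.labels)
        assert np.allclose(a.coassignment, b.coassignment)

    def test_consensus_idempotent_on_binary_blocks(self):
        labels = np.repeat([0, 1, 2], [5, 4, 3])
        D = (labels[:, None] == labels[None, :]).astype(float)
        cp = consensus_cluster(D, ClusteringConfig(gamma=1.0, n_iterations=20,
                                                   seed=0))
        assert adjusted_rand_score(cp.labels, labels) == 1.0
        assert cp.rounds == 1

    def test_row_permutation_equivariance(self, block_similarity):
        S, _ = block_similarity
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(S))
        cfg = ClusteringConfig(gamma=1.0, n_iterations=30, seed=4)
        a = consensus_cluster(S, cfg)
        b = consensus_cluster(S[np.ix_(perm, perm)], cfg)
        assert adjusted_rand_score(a.labels[perm], b.labels) == 1.0

    def test_archive_reproduces_coassignment(self, two_triangles):
        cp = consensus_cluster(two_triangles,
                               ClusteringConfig(gamma=1.0, n_iterations=25,
                                                seed=3),
                               keep_partitions=True)
        D = np.zeros((6, 6))
        for lab in cp.partitions:
            D += lab[:, None] == lab[None, :]
        D /= len(cp.partitions)
        np.fill_diagonal(D, 1.0)
        assert np.allclose(D, cp.coassignment)


class TestGammaSearch:
    def test_two_cliques(self, two_triangles):
        cfg = ClusteringConfig(gamma=1.0, n_iterations=20, seed=0)
        g, part = gamma_search(two_triangles, 2, [1.0], cfg)
        assert g == 1.0 and part.n_clusters == 2

    def test_planted_blocks_smallest_gamma(self, block_similarity):
        S, _ = block_similarity
        cfg = ClusteringConfig(gamma=1.0, n_iterations=30, seed=2)
        grid = [0.8, 1.0, 1.2, 1.4]
        g, part = gamma_search(S, 4, grid, cfg)
        assert part.n_clusters == 4
        # exhaustive verification that no smaller grid gamma yields 4
        for smaller in [x for x in grid if x < g]:
            cp = consensus_cluster(S, ClusteringConfig(
                gamma=smaller, n_iterations=30, seed=2))
            assert cp.n_clusters != 4

    def test_target_exceeds_n(self, two_triangles):
        cfg = ClusteringConfig(gamma=1.0, n_iterations=10, seed=0)
        with pytest.raises(GammaSearchError):
            gamma_search(two_triangles, 10, [1.0], cfg)

    def test_no_solution_lists_k(self, two_triangles):
        cfg = ClusteringConfig(gamma=1.0, n_iterations=10, seed=0)
        with pytest.raises(GammaSearchError, match="k\\(1\\)=2"):
            gamma_search(two_triangles, 5, [1.0], cfg)

    def test_default_grid_shape(self):
        grid = default_gamma_grid()
        assert grid[0] == 0.8 and grid[-1] == 2.0
        assert np.allclose(np.diff(grid), 0.02)


class TestConfig:
    @pytest.mark.parametrize("kwargs", [
        {"gamma": 0.0}, {"gamma": -1.0}, {"coassignment_threshold": 1.0},
        {"n_iterations": 0}, {"negative_weight_policy": "bogus"}])
    def test_invalid(self, kwargs):
        with pytest.raises(ValueError):
            ClusteringConfig(**kwargs)

    def test_signed_policy_runs(self, block_similarity):
        S, truth = block_similarity
        S2 = S - 0.3  # force negative weights
        np.fill_diagonal(S2, 1.0)
        res = louvain(S2, 1.0, seed=0, negative_weight_policy="signed")
        assert adjusted_rand_score(res.labels, truth) == 1.0

    def test_canonicalize(self):
        out = canonicalize_labels(np.array([9, 9, 9, 2, 2, 7]))
        assert out.tolist() == [1, 1, 1, 2, 2, 3]
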