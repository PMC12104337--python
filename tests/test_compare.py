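import numpy as np
import pandas as pd
import pytest
from scipy import stats

from adsubtype.compare import (allocation_overlap, cluster_roi_profile,
                               contrast_map, crossmodal_spearman,
                               most_least_maps, vertexwise_correlation)
from adsubtype.normalization import fit_reference, parcel_means, vertex_zscores
from adsubtype.synthetic import CohortSpec, generate_cohort


class TestAllocationOverlap:
    def test_identical_partitions_hand_chi2(self):
        p = [1] * 10 + [2] * 10
        table = allocation_overlap(p, p)
        assert table.counts.to_numpy().tolist() == [[10, 0], [0, 10]]
        assert table.chi2 == pytest.approx(20.0)
        assert table.df == 1

    def test_chi2_matches_hand_formula(self):
        rng = np.random.default_rng(3)
        for _ in range(20):
            p = rng.integers(1, 4, 120)
            q = rng.integers(1, 4, 120)
            table = allocation_overlap(p, q)
            obs = table.counts.to_numpy().astype(float)
            exp = (obs.sum(1, keepdims=True) * obs.sum(0, keepdims=True)
                   / obs.sum())
            assert table.chi2 == pytest.approx(((obs - exp) ** 2 / exp).sum(),
                                               abs=1e-9)

    def test_null_p_uniform(self):
        rng = np.random.default_rng(0)
        pvals = []
        for _ in range(500):
            p = rng.integers(1, 5, 160)
            q = rng.integers(1, 5, 160)
            pvals.append(allocation_overlap(p, q).p_value)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_single_cluster_degenerate(self):
        with pytest.raises(ValueError, match="degenerate"):
            allocation_overlap([1] * 20, [1] * 10 + [2] * 10)

    def test_row_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        p, q = rng.integers(1, 5, 100), rng.integers(1, 5, 100)
        table = allocation_overlap(p, q)
        assert np.allclose(table.row_fractions.sum(axis=1), 1.0)

    def test_length_mismatch(self):
        with pytest.raises(ValueError):
            allocation_overlap([1, 2], [1, 2, 3])


class TestClusterRoiProfile:
    def test_singleton_cluster_identity(self):
        z = pd.DataFrame([[1.0, 2.0], [5.0, 6.0]], index=["a", "b"],
                         columns=["r1", "r2"])
        prof = cluster_roi_profile(z, [1, 2])
        assert prof.loc[1].tolist() == [1.0, 2.0]

    def test_symmetric_rows_cancel(self):
        v = np.array([1.0, -2.0, 3.0])
        z = pd.DataFrame([v, -v], index=["a", "b"], columns=["r1", "r2", "r3"])
        prof = cluster_roi_profile(z, [1, 1])
        assert np.allclose(prof.loc[1], 0.0)

    def test_groupby_oracle(self):
        rng = np.random.default_rng(2)
        z = pd.DataFrame(rng.normal(size=(30, 6)),
                         index=[f"s{i}" for i in range(30)])
        labels = rng.integers(1, 4, 30)
        prof = cluster_roi_profile(z, labels)
        for c in np.unique(labels):
            manual = z.to_numpy()[labels == c].mean(axis=0)
            assert np.allclose(prof.loc[c], manual, atol=1e-12)


class TestCrossmodalSpearman:
    def _profiles(self, rng, n_clusters=4, n_roi=20):
        data = rng.normal(size=(n_clusters, n_roi))
        cols = [f"roi{i}" for i in range(n_roi)]
        return pd.DataFrame(data, index=range(1, n_clusters + 1), columns=cols)

    def test_sign_corrected_negation_gives_one(self):
        rng = np.random.default_rng(0)
        tau = self._profiles(rng)
        atrophy = -tau  # thickness z: more atrophy = more negative
        res = crossmodal_spearman(tau, atrophy)
        assert np.allclose(np.diag(res.rho.to_numpy()), 1.0)

    def test_monotone_transform_invariance(self):
        rng = np.random.default_rng(1)
        tau = self._profiles(rng)
        atrophy = -tau
        res_a = crossmodal_spearman(tau, atrophy)
        res_b = crossmodal_spearman(np.exp(tau * 0.5), atrophy)
        assert np.allclose(res_a.rho, res_b.rho, atol=1e-12)

    def test_spearman_equals_pearson_of_ranks(self):
        rng = np.random.default_rng(5)
        tau = self._profiles(rng, 2, 30)
        atrophy = self._profiles(rng, 2, 30)
        res = crossmodal_spearman(tau, atrophy, flip_atrophy_sign=False)
        for i in tau.index:
            for j in atrophy.index:
                ra = stats.rankdata(tau.loc[i])
                rb = stats.rankdata(atrophy.loc[j])
                assert res.rho.loc[i, j] == pytest.approx(
                    np.corrcoef(ra, rb)[0, 1], abs=1e-12)

    def test_sign_correction_coherence(self):
        rng = np.random.default_rng(7)
        tau = self._profiles(rng)
        atrophy = self._profiles(rng)
        flipped = crossmodal_spearman(tau, atrophy, flip_atrophy_sign=True)
        manual = crossmodal_spearman(tau, -atrophy, flip_atrophy_sign=False)
        assert np.allclose(flipped.rho, manual.rho, atol=1e-12)

    def test_too_few_rois(self):
        rng = np.random.default_rng(0)
        tau = self._profiles(rng, 4, 4)
        with pytest.raises(ValueError, match="shared ROI"):
            crossmodal_spearman(tau, tau)

    def test_planted_coupling(self):
        matched_min, mismatched = [], []
        for seed in range(3):
            spec = CohortSpec(n_hc=50, n_ads=60, cluster_sizes=(15,) * 4,
                              n_vertices=400, crossmodal_discordance=0.0,
                              seed=seed)
            ds = generate_cohort(spec)
            prof = {}
            for m, mat, col in (("tau", ds.tau, "tau_cluster"),
                                ("atr", ds.thickness, "atrophy_cluster")):
                ref = fit_reference(mat.loc[ds.hc_ids])
                z = vertex_zscores(mat.loc[ds.ads_ids], ref)
                prof[m] = cluster_roi_profile(parcel_means(z, ds.parcels),
                                              ds.truth[col].to_numpy())
            rho = crossmodal_spearman(prof["tau"], prof["atr"]).rho.to_numpy()
            matched_min.append(np.diag(rho).min())
            mismatched.append(np.abs(rho[~np.eye(4, dtype=bool)]).mean())
        assert min(matched_min) >= 0.8
        assert max(mismatched) <= 0.3


class TestContrastMap:
    def test_planted_shift_power(self):
        rng = np.random.default_rng(0)
        Z = rng.normal(size=(60, 200))
        Z[:30, :20] += 2.0
        cm = contrast_map(Z, np.arange(30), np.arange(30, 60), n_perm=500,
                          seed=1)
        assert cm.mask[:20].mean() >= 0.9

    def test_null_rarely_significant(self):
        hits = 0
        for sim in range(40):
            rng = np.random.default_rng(100 + sim)
            Z = rng.normal(size=(40, 100))
            cm = contrast_map(Z, np.arange(20), np.arange(20, 40),
                              n_perm=200, seed=sim)
            hits += cm.mask.any()
        assert hits / 40 <= 0.15  # loose band; tight calibration in acceptance

    def test_min_permutations_guard(self):
        Z = np.random.default_rng(0).normal(size=(10, 5))
        with pytest.raises(ValueError, match="n_perm"):
            contrast_map(Z, np.arange(5), np.arange(5, 10), n_perm=0)

    def test_disjoint_groups_required(self):
        Z = np.random.default_rng(0).normal(size=(10, 5))
        with pytest.raises(ValueError, match="disjoint"):
            contrast_map(Z, np.arange(6), np.arange(4, 10), n_perm=100)

    def test_dataframe_ids(self):
        rng = np.random.default_rng(1)
        z = pd.DataFrame(rng.normal(size=(12, 8)),
                         index=[f"s{i}" for i in range(12)])
        cm = contrast_map(z, [f"s{i}" for i in range(6)],
                          [f"s{i}" for i in range(6, 12)], n_perm=100)
        assert cm.t_stat.shape == (8,)


class TestMostLeastMaps:
    def test_planted_patterns_overlap_truth(self):
        spec = CohortSpec(n_hc=50, n_ads=60, cluster_sizes=(15,) * 4,
                          n_vertices=200, effect_size=3.0, seed=31)
        ds = generate_cohort(spec)
        ref = fit_reference(ds.tau.loc[ds.hc_ids])
        z = vertex_zscores(ds.tau.loc[ds.ads_ids], ref)
        labels = ds.truth["tau_cluster"].to_numpy()
        maps = most_least_maps(z, labels, n_perm=300, seed=0)
        for c, pair in maps.items():
            planted = set(np.flatnonzero(ds.tau_masks[c - 1]))
            found = set(np.flatnonzero(pair["most"].mask))
            jaccard = len(planted & found) / len(planted | found)
            assert jaccard >= 0.5

    def test_single_cluster_warns(self):
        z = pd.DataFrame(np.random.default_rng(0).normal(size=(10, 5)))
        with pytest.warns(UserWarning, match="single cluster"):
            out = most_least_maps(z, [1] * 10, n_perm=100)
        assert out == {}

    def test_singleton_cluster_skipped(self):
        z = pd.DataFrame(np.random.default_rng(0).normal(size=(11, 5)))
        with pytest.warns(UserWarning, match="skipped"):
            out = most_least_maps(z, [1] * 5 + [2] * 5 + [3], n_perm=100)
        assert 3 not in out


class TestVertexwiseCorrelation:
    def test_exact_negation(self):
        rng = np.random.default_rng(0)
        A = rng.normal(size=(20, 10))
        res = vertexwise_correlation(A, -A, n_perm=100)
        assert np.allclose(res.t_stat, -1.0)

    def test_constant_column_excluded(self):
        rng = np.random.default_rng(1)
        A = rng.normal(size=(15, 4))
        B = rng.normal(size=(15, 4))
        B[:, 2] = 7.0
        with pytest.warns(UserWarning, match="constant"):
            res = vertexwise_correlation(A, B, n_perm=100)
        assert res.t_stat.shape == (3,)

    def test_min_subjects(self):
        A = np.zeros((3, 4))
        with pytest.raises(ValueError, match="subjects"):
            vertexwise_correlation(A, A, n_perm=100)

    def test_null_rate_loose(self):
        hits = 0
        for sim in range(40):
            rng = np.random.default_rng(sim)
            A = rng.normal(size=(30, 50))
            B = rng.normal(size=(30, 50))
            res = vertexwise_correlation(A, B, n_perm=200, seed=sim)
            hits += res.mask.any()
        assert hits / 40 <= 0.15
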