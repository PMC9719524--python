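"""Strict autosomal filtering, PCA, F_ST, Nei distance and AMOVA."""

import numpy as np
import pandas as pd
import pytest

from sexlinkscan.io import HET, HOM_ALT, HOM_REF, MISSING, SnpMatrix
from sexlinkscan.simulate import SimConfig, simulate_dataset
from sexlinkscan.structure import (
    allele_sharing_distance, amova, filter_autosomal_strict,
    mean_within_cluster_distance, nei_distance, nei_distance_from_frequencies,
    pairwise_fst, pca_scores,
)

from conftest import make_snp


def snp_with_meta(calls, rep_avg):
    calls = np.asarray(calls, dtype=np.int8)
    ids = [f"L{i}" for i in range(calls.shape[0])]
    meta = pd.DataFrame({"rep_avg": rep_avg}, index=pd.Index(ids))
    return make_snp(calls, locus_ids=ids, meta=meta)


class TestStrictAutosomalFilter:
    def test_imperfect_call_rate_dropped(self):
        calls = [[HOM_REF, HET, MISSING], [HOM_REF, HET, HOM_ALT]]
        m = snp_with_meta(calls, [1.0, 1.0])
        out = filter_autosomal_strict(m, [])
        assert list(out.locus_ids) == ["L1"]

    def test_sexlinked_locus_dropped_despite_perfect_metrics(self):
        calls = [[HOM_REF, HET, HOM_ALT], [HOM_REF, HET, HOM_ALT]]
        m = snp_with_meta(calls, [1.0, 1.0])
        out = filter_autosomal_strict(m, ["L0"])
        assert list(out.locus_ids) == ["L1"]

    def test_imperfect_reproducibility_dropped(self):
        calls = [[HOM_REF, HET], [HOM_REF, HET]]
        m = snp_with_meta(calls, [0.99, 1.0])
        assert list(filter_autosomal_strict(m, []).locus_ids) == ["L1"]

    def test_complete_simulation_fully_retained(self):
        ds = simulate_dataset(SimConfig(n_males=5, n_females=5,
                                        n_autosomal=100, seed=2))
        out = filter_autosomal_strict(ds.snp, [])
        assert out.n_loci == 100

    def test_empty_result_is_hard_error(self):
        calls = [[HOM_REF, MISSING]]
        m = snp_with_meta(calls, [1.0])
        with pytest.raises(ValueError, match="every locus"):
            filter_autosomal_strict(m, [])


class TestPca:
    def test_two_clusters_separate_on_pc1(self, two_cluster_dataset):
        ds = two_cluster_dataset
        res = pca_scores(ds.snp)
        labels = ds.sheet.cluster_of(ds.snp.sample_ids)
        pc1 = res.scores["PC1"].to_numpy()
        a, b = pc1[labels == 1], pc1[labels == 2]
        # zero overlap in PC1 score ranges
        assert (a.max() < b.min()) or (b.max() < a.min())

    def test_duplicate_sample_gets_identical_scores(self):
        rng = np.random.default_rng(4)
        calls = rng.integers(0, 3, size=(50, 6)).astype(np.int8)
        calls[:, 5] = calls[:, 0]
        res = pca_scores(make_snp(calls))
        np.testing.assert_allclose(res.scores.iloc[0], res.scores.iloc[5],
                                   atol=1e-8)

    def test_explained_variance_non_increasing_and_bounded(self, two_cluster_dataset):
        res = pca_scores(two_cluster_dataset.snp)
        ev = res.explained_variance_ratio
        assert (np.diff(ev) <= 1e-12).all()
        assert ev.sum() <= 1.0 + 1e-9

    def test_single_cluster_pc1_not_dominant(self):
        ds = simulate_dataset(SimConfig(n_males=10, n_females=10,
                                        n_autosomal=2000, seed=6))
        ev = pca_scores(ds.snp).explained_variance_ratio
        assert ev[0] < 3 * ev[1]

    def test_scores_invariant_to_sample_order_up_to_sign(self):
        rng = np.random.default_rng(8)
        calls = rng.integers(0, 3, size=(60, 8)).astype(np.int8)
        m = make_snp(calls)
        perm = rng.permutation(8)
        m2 = m.subset_samples(m.sample_ids[perm])
        s1 = pca_scores(m).scores.loc[list(m2.sample_ids)].to_numpy()
        s2 = pca_scores(m2).scores.to_numpy()
        for k in range(s1.shape[1]):
            assert (np.allclose(s1[:, k], s2[:, k], atol=1e-8)
                    or np.allclose(s1[:, k], -s2[:, k], atol=1e-8))

    def test_constant_matrix_rejected(self):
        m = make_snp(np.full((5, 4), HET, dtype=np.int8))
        with pytest.raises(ValueError, match="constant"):
            pca_scores(m)


class TestFst:
    def test_identical_frequency_clusters_near_zero(self):
        ds = simulate_dataset(SimConfig(n_males=10, n_females=10, n_clusters=2,
                                        fst_target=0.0, n_autosomal=5000,
                                        seed=3))
        labels = ds.sheet.cluster_of(ds.snp.sample_ids)
        est = pairwise_fst(ds.snp, labels)["fst"].iloc[0]
        assert abs(est) < 0.01

    def test_fixed_opposite_clusters_near_one(self):
        calls = np.array([[HOM_REF] * 4 + [HOM_ALT] * 4] * 20, dtype=np.int8)
        m = make_snp(calls)
        est = pairwise_fst(m, [1] * 4 + [2] * 4)["fst"].iloc[0]
        assert est == pytest.approx(1.0, abs=1e-9)

    def test_divergence_target_recovered(self, two_cluster_dataset):
        ds = two_cluster_dataset
        labels = ds.sheet.cluster_of(ds.snp.sample_ids)
        est = pairwise_fst(ds.snp, labels)["fst"].iloc[0]
        assert est == pytest.approx(0.24, abs=0.05)

    def test_monotone_in_divergence(self):
        """Average F_ST estimate increases with the generating divergence."""
        means = []
        for target in (0.05, 0.1, 0.2, 0.4):
            ests = []
            for seed in range(3):
                ds = simulate_dataset(SimConfig(
                    n_males=8, n_females=8, n_clusters=2, fst_target=target,
                    n_autosomal=800, seed=100 + seed))
                labels = ds.sheet.cluster_of(ds.snp.sample_ids)
                ests.append(pairwise_fst(ds.snp, labels)["fst"].iloc[0])
            means.append(np.mean(ests))
        assert all(np.diff(means) > 0)

    def test_monomorphic_only_is_undefined(self):
        m = make_snp(np.full((5, 6), HOM_REF, dtype=np.int8))
        with pytest.warns(UserWarning, match="F_ST"):
            est = pairwise_fst(m, [1, 1, 1, 2, 2, 2])["fst"].iloc[0]
        assert np.isnan(est)


class TestNei:
    def test_identical_clusters_zero(self):
        calls = np.array([[HOM_REF, HET, HOM_REF, HET],
                          [HET, HOM_ALT, HET, HOM_ALT]], dtype=np.int8)
        m = make_snp(calls)
        d = nei_distance(m, [1, 1, 2, 2])["nei_d"].iloc[0]
        assert d == pytest.approx(0.0, abs=1e-12)

    def test_hand_computed_two_locus_value(self):
        # locus 1: p = 0.5 in both; locus 2: p = 0.9 vs 0.1
        # J_x = J_y = (0.5 + 0.82) / 2 = 0.66
        # J_xy = (0.5 + 2 * 0.09) / 2 = 0.34 -> D = ln(0.66 / 0.34)
        d = nei_distance_from_frequencies([0.5, 0.9], [0.5, 0.1])
        assert d == pytest.approx(np.log(0.66 / 0.34), rel=1e-12)

    def test_individual_self_distance_zero(self):
        rng = np.random.default_rng(2)
        calls = rng.integers(0, 3, size=(30, 5)).astype(np.int8)
        dm = allele_sharing_distance(make_snp(calls))
        assert (np.diag(dm) == 0).all()

    def test_within_cluster_mean_distance_ordering(self):
        """A more diverse cluster shows a larger mean individual distance."""
        rng = np.random.default_rng(9)
        # cluster 1: random genotypes; cluster 2: near-identical individuals
        c1 = rng.integers(0, 3, size=(100, 6)).astype(np.int8)
        c2 = np.tile(rng.integers(0, 3, size=(100, 1)), (1, 6)).astype(np.int8)
        m = make_snp(np.hstack([c1, c2]),
                     sample_ids=[f"S{j}" for j in range(12)])
        d = mean_within_cluster_distance(m, [1] * 6 + [2] * 6)
        assert d[1] > d[2]
        assert d[2] == pytest.approx(0.0)


class TestAmova:
    def make_two_cluster(self, seed=0, n_loci=300, n1=6, n2=4, fst=0.3):
        ds = simulate_dataset(SimConfig(
            n_males=max(n1, n2) // 2 + 1, n_females=max(n1, n2) // 2 + 1,
            n_clusters=2, fst_target=fst, n_autosomal=n_loci, seed=seed))
        return ds

    def test_df_pattern_and_percent_sum(self):
        ds = simulate_dataset(SimConfig(n_males=11, n_females=11, n_clusters=2,
                                        fst_target=0.2, n_autosomal=400,
                                        seed=5))
        labels = ds.sheet.cluster_of(ds.snp.sample_ids)
        res = amova(ds.snp, labels, permutations=0)
        n, k = 44, 2
        assert res.table["df"].tolist() == [k - 1, n - k, n, 2 * n - 1]
        assert res.table.loc["total", "percent_variance"] == pytest.approx(
            100.0, abs=1e-6)
        sig = res.table["sigma"]
        assert sig.iloc[:3].sum() == pytest.approx(sig.loc["total"])
        assert (sig.iloc[:3] >= 0).all()

    def test_ss_matches_pairwise_distance_oracle(self):
        """Centroid sums of squares equal the classic pairwise-squared-
        distance formulation SS = sum_{i<j} d2_ij / n."""
        ds = simulate_dataset(SimConfig(n_males=3, n_females=3, n_clusters=2,
                                        fst_target=0.3, n_autosomal=40,
                                        seed=7))
        labels = ds.sheet.cluster_of(ds.snp.sample_ids)
        res = amova(ds.snp, labels, permutations=0)

        from sexlinkscan.structure import _allele_vectors
        alleles = _allele_vectors(ds.snp)
        n_a = alleles.shape[0]

        def ss_pairwise(x):
            d2 = ((x[:, None, :] - x[None, :, :]) ** 2).sum(axis=2)
            iu = np.triu_indices(len(x), k=1)
            return d2[iu].sum() / len(x)

        ss_total = ss_pairwise(alleles)
        cluster_of_allele = np.repeat(labels, 2)
        ss_wc = sum(ss_pairwise(alleles[cluster_of_allele == g])
                    for g in (1, 2))
        ind = np.repeat(np.arange(ds.snp.n_samples), 2)
        ss_wi = sum(ss_pairwise(alleles[ind == i])
                    for i in range(ds.snp.n_samples))
        assert res.table.loc["total", "sum_sq"] == pytest.approx(ss_total)
        assert res.table.loc["between_clusters", "sum_sq"] == pytest.approx(
            ss_total - ss_wc)
        assert res.table.loc["between_samples_within_clusters", "sum_sq"] == \
            pytest.approx(ss_wc - ss_wi)
        assert res.table.loc["within_samples", "sum_sq"] == pytest.approx(ss_wi)

    def test_true_clusters_significant_random_labels_not(self):
        ds = simulate_dataset(SimConfig(n_males=8, n_females=8, n_clusters=2,
                                        fst_target=0.25, n_autosomal=500,
                                        seed=12))
        labels = ds.sheet.cluster_of(ds.snp.sample_ids)
        res = amova(ds.snp, labels, permutations=99, seed=0)
        assert res.p_between_clusters <= 0.05
        assert res.table.loc["between_clusters", "percent_variance"] > 5

        rng = np.random.default_rng(3)
        rand = rng.permutation(labels)
        null = amova(ds.snp, rand, permutations=99, seed=0)
        assert null.table.loc["between_clusters", "percent_variance"] < \
            res.table.loc["between_clusters", "percent_variance"]

    def test_null_labels_between_cluster_percent_near_zero(self):
        """Random labels on a single population: the between-cluster component
        is truncated at (or near) zero and p is typically non-significant."""
        hits = 0
        pcts = []
        for seed in range(5):
            ds = simulate_dataset(SimConfig(n_males=8, n_females=8,
                                            n_autosomal=300, seed=30 + seed))
            rng = np.random.default_rng(seed)
            labels = rng.permutation([1] * 8 + [2] * 8)
            res = amova(ds.snp, labels, permutations=49, seed=seed)
            pcts.append(res.table.loc["between_clusters", "percent_variance"])
            hits += res.p_between_clusters <= 0.05
        assert np.mean(pcts) < 3.0
        assert hits <= 1

    def test_cluster_of_one_rejected(self):
        ds = simulate_dataset(SimConfig(n_males=2, n_females=2,
                                        n_autosomal=20, seed=1))
        with pytest.raises(ValueError, match="two individuals"):
            amova(ds.snp, [1, 1, 1, 2], permutations=0)

    def test_missing_calls_rejected(self):
        calls = np.array([[HOM_REF, HET, MISSING, HOM_ALT]] * 3, dtype=np.int8)
        with pytest.raises(ValueError, match="complete"):
            amova(make_snp(calls), [1, 1, 2, 2], permutations=0)
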