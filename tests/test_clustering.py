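"""Clustering: z-scores, scree rule, Rand index, stability, enrichment."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy.special import gammaln, logsumexp

from proteoage import (
    NPXMatrix,
    ProteinClustering,
    ValidationError,
    rand_index,
    scree_select_k,
    simulate_clusters,
    zscore_proteins,
)
from proteoage.clustering import hypergeom_logsf, hypergeom_sf


def brute_force_rand(a, b):
    """Exhaustive pair enumeration, straight from the definition."""
    agree = total = 0
    for i, j in itertools.combinations(range(len(a)), 2):
        total += 1
        agree += (a[i] == a[j]) == (b[i] == b[j])
    return agree / total


class TestZScore:
    def test_hand_computation_with_sample_sd(self):
        matrix = NPXMatrix(
            pd.DataFrame({"P00001": [1.0, 2.0, 3.0]}, index=["a", "b", "c"])
        )
        z = zscore_proteins(matrix)
        assert np.allclose(z.data["P00001"], [-1.0, 0.0, 1.0])  # sd(n-1) = 1

    def test_idempotence(self):
        rng = np.random.default_rng(3)
        matrix = NPXMatrix(
            pd.DataFrame(
                rng.normal(size=(20, 5)),
                index=[f"s{i}" for i in range(20)],
                columns=[f"P{j:05d}" for j in range(1, 6)],
            )
        )
        once = zscore_proteins(matrix)
        twice = zscore_proteins(once)
        assert np.allclose(once.data.to_numpy(), twice.data.to_numpy(), atol=1e-12)

    def test_constant_protein_dropped_with_warning(self):
        matrix = NPXMatrix(
            pd.DataFrame(
                {"P00001": [1.0, 2.0, 3.0], "P00002": [5.0, 5.0, 5.0]},
                index=["a", "b", "c"],
            )
        )
        with pytest.warns(UserWarning, match="constant"):
            z = zscore_proteins(matrix)
        assert z.protein_ids == ["P00001"]
        with pytest.raises(ValidationError):
            zscore_proteins(
                NPXMatrix(pd.DataFrame({"P00001": [1.0, 1.0]}, index=["a", "b"]))
            )


class TestScreeSelect:
    def test_dominant_jump_leaving_four_groups(self):
        # three large merges (cutting them leaves 4 groups), then a plateau
        heights = [10.0, 9.5, 9.0, 2.0, 1.9, 1.8, 1.7, 1.6]
        assert scree_select_k(heights) == 4

    def test_linear_heights_default_to_two_with_warning(self):
        with pytest.warns(UserWarning, match="flat"):
            assert scree_select_k(np.linspace(1, 10, 12)) == 2

    def test_needs_three_merges(self):
        with pytest.raises(ValidationError):
            scree_select_k([1.0, 2.0])


class TestRandIndex:
    def test_identical_partitions(self):
        assert rand_index([1, 1, 2, 2], [1, 1, 2, 2]) == 1.0

    def test_crossed_two_by_two(self):
        # brute force: only the pairs (1,4) and (2,3) agree -> 2/6
        assert rand_index([1, 1, 2, 2], [1, 2, 1, 2]) == pytest.approx(2 / 6)

    def test_matches_brute_force_on_random_partitions(self):
        rng = np.random.default_rng(11)
        for _ in range(500):
            n = rng.integers(2, 50)
            a = rng.integers(0, 5, size=n)
            b = rng.integers(0, 5, size=n)
            assert rand_index(a, b) == pytest.approx(brute_force_rand(a, b))

    def test_singleton_vs_k_partition_closed_form(self):
        b = np.array([0, 0, 1, 1, 1, 2])
        n = len(b)
        within = sum(
            c * (c - 1) / 2 for c in np.bincount(b)
        )
        expected = (n * (n - 1) / 2 - within) / (n * (n - 1) / 2)
        assert rand_index(np.arange(n), b) == pytest.approx(expected)

    def test_mismatched_lengths_rejected(self):
        with pytest.raises(ValidationError):
            rand_index([1, 2], [1, 2, 3])


class TestHypergeometricTail:
    def test_agrees_with_log_space_pmf_summation(self):
        rng = np.random.default_rng(2)
        for _ in range(200):
            N = int(rng.integers(10, 2000))
            K = int(rng.integers(1, N))
            n = int(rng.integers(1, N))
            k = int(rng.integers(0, min(K, n) + 1))
            p = hypergeom_sf(k, N, K, n)
            logp = hypergeom_logsf(k, N, K, n)
            if p > 0:
                assert np.log(p) == pytest.approx(logp, abs=1e-10)

    def test_exhaustive_enumeration_small_case(self):
        # P(X >= 10 | N=50, K=10, n=10) = C(10,10) C(40,0) / C(50,10)
        expected = np.exp(
            gammaln(41) + gammaln(11) - gammaln(51) - gammaln(1)
        )  # 40!10!/50!... = 1/C(50,10)
        assert hypergeom_sf(10, 50, 10, 10) == pytest.approx(expected, rel=1e-10)

    def test_zero_overlap_gives_p_one(self):
        assert hypergeom_sf(0, 100, 10, 10) == 1.0


class TestClusteringModel:
    def test_two_separated_blobs_split_exactly(self):
        matrix, truth = simulate_clusters(40, 2, 5.0, seed=0)
        fit = ProteinClustering(matrix).fit(k=2)
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(truth.loc[fit.labels.index], fit.labels) == 1.0

    @pytest.mark.parametrize("seed", range(5))
    def test_auto_k_recovers_four_planted_clusters(self, seed):
        matrix, truth = simulate_clusters(120, 4, 4.0, seed=seed)
        fit = ProteinClustering(matrix).fit()
        from sklearn.metrics import adjusted_rand_score

        assert fit.auto_k == 4
        assert adjusted_rand_score(truth.loc[fit.labels.index], fit.labels) == 1.0

    def test_input_order_invariance(self):
        matrix, _ = simulate_clusters(50, 3, 3.0, seed=2)
        shuffled = NPXMatrix(matrix.data.sample(frac=1, axis=1, random_state=5))
        fit1 = ProteinClustering(matrix).fit(k=3)
        fit2 = ProteinClustering(shuffled).fit(k=3)
        from sklearn.metrics import adjusted_rand_score

        common = sorted(fit1.labels.index)
        assert (
            adjusted_rand_score(fit1.labels[common], fit2.labels[common]) == 1.0
        )

    def test_euclidean_vs_manhattan_mostly_agree(self):
        matrix, _ = simulate_clusters(120, 4, 4.0, seed=7)
        fit_e = ProteinClustering(matrix, distance="euclidean").fit(k=4)
        fit_m = ProteinClustering(matrix, distance="manhattan").fit(k=4)
        # fraction of protein pairs co-assigned identically in both runs
        assert rand_index(fit_e.labels, fit_m.labels[fit_e.labels.index]) >= 0.9

    def test_k_larger_than_panel_rejected(self):
        matrix, _ = simulate_clusters(10, 2, 1.0, seed=0)
        with pytest.raises(ValidationError):
            ProteinClustering(matrix).fit(k=11)


class TestStability:
    def test_separated_clusters_are_maximally_stable(self):
        matrix, _ = simulate_clusters(120, 4, 4.0, seed=1)
        fit = ProteinClustering(matrix).fit(k=4)
        scores = fit.stability(n_repeats=20, n_baseline=30, seed=0).scores()
        assert (scores["normalized_score"] >= 0.95).all()

    def test_pure_noise_scores_near_chance(self):
        vals = []
        for seed in range(5):
            matrix, _ = simulate_clusters(80, 2, 0.0, seed=seed)
            fit = ProteinClustering(matrix).fit()
            scores = fit.stability(n_repeats=10, n_baseline=30, seed=seed).scores()
            vals.append(scores["normalized_score"].mean())
        # residual positive score reflects data overlap between the
        # subsample and the reference partition, not real structure
        assert abs(np.mean(vals)) <= 0.2

    def test_fixed_seed_reproducible(self):
        matrix, _ = simulate_clusters(40, 2, 2.0, seed=3)
        fit = ProteinClustering(matrix).fit(k=2)
        t1 = fit.stability(n_repeats=3, n_baseline=10, seed=9).table
        t2 = fit.stability(n_repeats=3, n_baseline=10, seed=9).table
        pd.testing.assert_frame_equal(t1, t2)

    def test_per_k_stability_curve_peaks_at_true_k(self):
        from proteoage import stability_by_k

        matrix, _ = simulate_clusters(80, 3, 4.0, seed=4)
        model = ProteinClustering(matrix)
        curve = stability_by_k(model, k_values=(2, 3, 5), proportions=(0.9,),
                               n_repeats=8, n_baseline=20, seed=0)
        by_k = curve.set_index("k")["normalized_score"]
        assert by_k[3] >= 0.95
        assert by_k[3] >= by_k[5]

    def test_subsample_smaller_than_k_rejected(self):
        matrix, _ = simulate_clusters(12, 2, 2.0, seed=0)
        fit = ProteinClustering(matrix).fit(k=10)
        with pytest.raises(ValidationError):
            fit.stability(proportions=(0.5,), n_repeats=1)


class TestEnrichment:
    def test_hypergeometric_counts_and_bh(self, assignment, small_cohort):
        matrix, _, _ = small_cohort
        fit = ProteinClustering(matrix).fit(k=3)
        table = fit.enrichment(assignment)
        assert set(table["category"]) == {"chronological_only", "disease_only", "ap"}
        assert (table["k"] <= np.minimum(table["K"], table["n"])).all()
        assert ((table["p_raw"] > 0) & (table["p_raw"] <= 1)).all()
        assert (table["p_adj"] >= table["p_raw"] - 1e-15).all()
        zero_rows = table[table["k"] == 0]
        assert (zero_rows["p_raw"] == 1.0).all()
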