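import numpy as np
import pytest
from scipy.stats import chi2_contingency

import goclust as gc
from goclust.evaluate import _bhi_from_subtable


def brute_force_bhi(T, cluster):
    """Independent double-sum evaluation of the homogeneity indicator on the
    cluster-restricted table (written against the definition, not the
    vectorised path)."""
    idx = [T.genes.index(g) for g in cluster]
    sub = T.values[idx].astype(float)
    keep = [j for j in range(sub.shape[1]) if sub[:, j].sum() > 0]
    sub = sub[:, keep]
    n = len(idx)
    total = sub.sum()
    chi2 = 0.0
    for a in range(sub.shape[0]):
        for b in range(sub.shape[1]):
            e = sub[a].sum() * sub[:, b].sum() / total
            chi2 += (sub[a, b] - e) ** 2 / e
    return 1.0 - chi2 / (total * (n - 1))


class TestCoexpressionIndicator:
    def test_shared_profile_up_to_affine_maps_gives_one(self):
        x = np.array([1.0, 4.0, 2.0, 8.0, 5.0])
        values = np.vstack([x, 3 * x + 1, 0.5 * x - 2])
        G = gc.ExpressionMatrix(["a", "b", "c"], [f"s{i}" for i in range(5)], values)
        assert gc.coexpression_indicator(G, ["a", "b", "c"]) == pytest.approx(1.0)

    def test_even_size_worst_case_reaches_minus_third(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        values = np.vstack([x, 2 * x, -x, -x + 1])
        G = gc.ExpressionMatrix(list("abcd"), [f"s{i}" for i in range(4)], values)
        # two perfect anti-correlated pairs: CI = -1/(n-1) = -1/3
        assert gc.coexpression_indicator(G, list("abcd")) == pytest.approx(-1 / 3)

    def test_odd_size_worst_case_reaches_minus_one_over_n(self):
        x = np.array([1.0, 2.0, 3.0, 4.0])
        values = np.vstack([x, 2 * x, -x])
        G = gc.ExpressionMatrix(list("abc"), [f"s{i}" for i in range(4)], values)
        # sub-groups of sizes 2 and 1: CI = -1/n = -1/3
        assert gc.coexpression_indicator(G, list("abc")) == pytest.approx(-1 / 3)

    def test_singleton_rejected(self, toy_expression):
        with pytest.raises(ValueError):
            gc.coexpression_indicator(toy_expression, ["g0"])


class TestBiologicalHomogeneityIndicator:
    def test_identical_profiles_give_one(self):
        values = np.array([[1, 1, 0], [1, 1, 0], [0, 1, 1], [1, 0, 1]])
        T = gc.AnnotationMatrix(list("abcd"), ["f1", "f2", "f3"], values)
        assert gc.biological_homogeneity_indicator(T, ["a", "b"]) == pytest.approx(1.0)

    def test_fully_private_profiles_give_zero(self):
        # every function annotated to exactly one cluster gene
        values = np.array([[1, 1, 0, 0], [0, 0, 1, 0], [0, 0, 0, 1]])
        T = gc.AnnotationMatrix(list("abc"), [f"f{j}" for j in range(4)], values)
        assert gc.biological_homogeneity_indicator(T, ["a", "b", "c"]) == pytest.approx(
            0.0, abs=1e-12
        )

    def test_hand_evaluated_three_gene_cluster(self, toy_annotation):
        cluster = ["g0", "g1", "g2"]
        assert gc.biological_homogeneity_indicator(
            toy_annotation, cluster
        ) == pytest.approx(brute_force_bhi(toy_annotation, cluster), abs=1e-12)

    def test_whole_universe_matches_contingency_statistic(self, toy_annotation):
        stat = chi2_contingency(toy_annotation.values, correction=False).statistic
        expected = 1.0 - stat / (toy_annotation.total * (toy_annotation.n_genes - 1))
        assert gc.biological_homogeneity_indicator(
            toy_annotation, list(toy_annotation.genes)
        ) == pytest.approx(expected, abs=1e-12)

    def test_unannotated_gene_named(self):
        values = np.array([[1, 1], [0, 0], [1, 0]])
        T = gc.AnnotationMatrix(list("abc"), ["f1", "f2"], values)
        with pytest.raises(ValueError, match="b"):
            gc.biological_homogeneity_indicator(T, ["a", "b"])


class TestPermutationPvalue:
    def test_observed_above_all_null_gives_zero(self, planted_dataset):
        G, truth = planted_dataset.G_sim, planted_dataset.block_truth
        block = [G.genes[k] for k in np.flatnonzero(truth == 0)]
        p = gc.permutation_pvalue(
            gc.coexpression_indicator, G, block, B=200, rng=np.random.default_rng(0)
        )
        assert p == 0.0

    def test_median_observation_near_half(self, unstructured_dataset):
        G = unstructured_dataset.G_sim
        rng = np.random.default_rng(1)
        # a random cluster from unstructured data sits near its null median
        ps = [
            gc.permutation_pvalue(
                gc.coexpression_indicator,
                G,
                [G.genes[k] for k in rng.choice(G.n_genes, 8, replace=False)],
                B=200,
                rng=rng,
            )
            for _ in range(40)
        ]
        assert 0.3 < float(np.median(ps)) < 0.7

    def test_singleton_not_tested(self, toy_expression):
        p = gc.permutation_pvalue(
            gc.coexpression_indicator, toy_expression, ["g0"], B=100,
            rng=np.random.default_rng(0),
        )
        assert p is None

    def test_invariant_to_gene_relabeling(self, planted_dataset):
        G, truth = planted_dataset.G_sim, planted_dataset.block_truth
        cluster_idx = np.flatnonzero(truth == 1)
        cluster = [G.genes[k] for k in cluster_idx]
        p1 = gc.permutation_pvalue(
            gc.coexpression_indicator, G, cluster, B=300, rng=np.random.default_rng(5)
        )
        renamed = [f"x{k}" for k in range(G.n_genes)]
        G2 = gc.ExpressionMatrix(renamed, list(G.samples), G.values.copy())
        p2 = gc.permutation_pvalue(
            gc.coexpression_indicator, G2, [renamed[k] for k in cluster_idx],
            B=300, rng=np.random.default_rng(5),
        )
        assert p1 == p2


class TestEvaluatePartition:
    def test_planted_partition_scores_near_perfect(self, planted_dataset):
        G, T, truth = (
            planted_dataset.G_sim,
            planted_dataset.T_sim,
            planted_dataset.block_truth,
        )
        part = gc.GenePartition(list(G.genes), truth)
        evals, summary = gc.evaluate_partition(
            G, T, part, B=300, rng=np.random.default_rng(0)
        )
        assert summary.pct_both >= 80.0
        assert all(e.ci_pvalue is not None for e in evals)

    def test_all_singletons_score_zero(self, planted_dataset):
        G, T = planted_dataset.G_sim, planted_dataset.T_sim
        part = gc.GenePartition(list(G.genes), np.arange(G.n_genes))
        evals, summary = gc.evaluate_partition(
            G, T, part, B=50, rng=np.random.default_rng(0)
        )
        assert summary.pct_ci == summary.pct_bhi == summary.pct_both == 0.0
        assert all(e.ci_pvalue is None and not e.significant_both for e in evals)

    def test_singletons_count_in_denominator(self, planted_dataset):
        G, T, truth = (
            planted_dataset.G_sim,
            planted_dataset.T_sim,
            planted_dataset.block_truth,
        )
        labels = truth.copy()
        labels[0] = truth.max() + 1  # carve out one singleton
        _, summary = gc.evaluate_partition(
            G, T, gc.GenePartition(list(G.genes), labels), B=200,
            rng=np.random.default_rng(0),
        )
        assert summary.n_clusters == truth.max() + 2
        assert summary.pct_both <= 100.0 * (summary.n_clusters - 1) / summary.n_clusters

    def test_universe_mismatch_rejected(self, planted_dataset, toy_annotation):
        G = planted_dataset.G_sim
        part = gc.GenePartition(list(G.genes), np.zeros(G.n_genes, dtype=int))
        with pytest.raises(ValueError):
            gc.evaluate_partition(G, toy_annotation, part, B=10)
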