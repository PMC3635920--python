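import numpy as np
import pytest
from scipy.cluster.hierarchy import fcluster, linkage
from scipy.spatial.distance import pdist

import goclust as gc
from goclust.decompose import CoexpAnnotationMatrix, FunctionPartition, _split_gene_set


def brute_force_best_cut(X, Z, l_max):
    """Independent search for the partition size with the largest relative
    drop of intra-cluster inertia (the oracle for the tree-cut rule)."""
    def inertia(labels):
        return sum(
            float(((X[labels == lab] - X[labels == lab].mean(0)) ** 2).sum())
            for lab in np.unique(labels)
        )

    W = {1: inertia(np.zeros(len(X), dtype=int))}
    for L in range(2, l_max + 1):
        W[L] = inertia(fcluster(Z, L, "maxclust"))
    losses = {L: (W[L - 1] - W[L]) / W[L - 1] for L in range(2, l_max + 1)}
    return min(L for L, v in losses.items() if v == max(losses.values()))


class TestCutTreeByRelativeInertia:
    def test_two_separated_blocks(self):
        rng = np.random.default_rng(0)
        X = np.vstack([rng.normal(0, 0.1, (8, 3)), rng.normal(5, 0.1, (8, 3))])
        Z = linkage(pdist(X), "ward")
        labels = gc.cut_tree_by_relative_inertia(Z, X, 6)
        assert len(np.unique(labels)) == 2
        assert len(np.unique(labels[:8])) == 1 and len(np.unique(labels[8:])) == 1

    def test_three_equidistant_blocks(self):
        rng = np.random.default_rng(1)
        centers = np.array([[0.0, 0.0], [10.0, 0.0], [5.0, 8.66]])
        X = np.vstack([c + rng.normal(0, 0.1, (9, 2)) for c in centers])
        Z = linkage(pdist(X), "ward")
        labels = gc.cut_tree_by_relative_inertia(Z, X, 8)
        assert len(np.unique(labels)) == 3
        assert len(np.unique(labels)) == brute_force_best_cut(X, Z, 8)

    def test_matches_brute_force_on_random_data(self):
        rng = np.random.default_rng(2)
        for _ in range(10):
            X = rng.standard_normal((20, 4))
            Z = linkage(pdist(X), "ward")
            labels = gc.cut_tree_by_relative_inertia(Z, X, 8)
            assert len(np.unique(labels)) == brute_force_best_cut(X, Z, 8)

    def test_pair_is_forced_split(self):
        X = np.array([[0.0, 0.0], [1.0, 1.0]])
        labels = _split_gene_set(X, 10)
        assert sorted(labels.tolist()) == [0, 1]


class TestStepZero:
    def test_planted_block_function_is_coexpressed(self, planted_dataset):
        G, truth = planted_dataset.G_sim, planted_dataset.block_truth
        genes = [G.genes[k] for k in np.flatnonzero(truth == 0)]
        rng = np.random.default_rng(0)
        flag, p = gc.test_function_coexpression(G, genes, B=500, rng=rng)
        assert flag and p < 0.01

    def test_uncorrelated_function_pvalues_spread(self, unstructured_dataset):
        # on unstructured data, random gene sets give roughly uniform p-values
        G = unstructured_dataset.G_sim
        rng = np.random.default_rng(1)
        corr = G.correlation_matrix()
        cache = gc.NullDistributionCache(corr, None, 500, rng)
        ps = []
        for _ in range(100):
            genes = [G.genes[k] for k in rng.choice(G.n_genes, 10, replace=False)]
            _, p = gc.test_function_coexpression(
                G, genes, B=500, rng=rng, corr=corr, cache=cache
            )
            ps.append(p)
        from scipy.stats import kstest

        assert kstest(ps, "uniform").statistic < 0.15

    def test_singleton_function_rejected(self, planted_dataset):
        with pytest.raises(ValueError):
            gc.test_function_coexpression(
                planted_dataset.G_sim, [planted_dataset.G_sim.genes[0]]
            )


class TestBuildTcoexp:
    def test_coexpressed_function_kept_whole(self, planted_dataset):
        G, truth = planted_dataset.G_sim, planted_dataset.block_truth
        block = [G.genes[k] for k in np.flatnonzero(truth == 0)]
        T = gc.build_annotation_matrix([(g, "fb") for g in block] * 1, list(G.genes))
        # add a second broad function so the matrix has > 1 column
        T = gc.build_annotation_matrix(
            [(g, "fb") for g in block] + [(g, "fall") for g in G.genes], list(G.genes)
        )
        tc, parts = gc.build_t_coexp(G, T, rng=np.random.default_rng(0))
        p_fb = next(p for p in parts if p.function == "fb")
        assert p_fb.coexpressed_whole and p_fb.L == 1

    def test_anticorrelated_function_split_recovers_blocks(self):
        # two anti-correlated 6-gene blocks share one function, embedded in a
        # larger universe of background noise genes (so the step-0 null is
        # drawn from genuinely different gene sets)
        rng = np.random.default_rng(4)
        x = rng.standard_normal(10)
        values = np.vstack(
            [x + rng.normal(0, 0.05, 10) for _ in range(6)]
            + [-x + rng.normal(0, 0.05, 10) for _ in range(6)]
            + [rng.standard_normal(10) for _ in range(24)]
        )
        G = gc.ExpressionMatrix(
            [f"g{k}" for k in range(36)], [f"s{i}" for i in range(10)], values
        )
        T = gc.build_annotation_matrix(
            [(g, "mix") for g in G.genes[:12]]
            + [(g, "other") for g in G.genes],
            list(G.genes),
        )
        tc, parts = gc.build_t_coexp(G, T, rng=np.random.default_rng(0))
        p_mix = next(p for p in parts if p.function == "mix")
        assert p_mix.L == 2
        assert {frozenset(c) for c in p_mix.sub_clusters} == {
            frozenset(G.genes[:6]),
            frozenset(G.genes[6:12]),
        }
        mix_margins = [
            m for (f, _), m in zip(tc.columns, tc.col_margins) if f == "mix"
        ]
        assert sum(mix_margins) == 12

    def test_margin_invariants_on_simulated_fixture(self, planted_dataset):
        G, T = planted_dataset.G_sim, planted_dataset.T_sim
        tc, _ = gc.build_t_coexp(G, T, rng=np.random.default_rng(0))
        assert np.array_equal(tc.row_margins, T.row_margins)
        assert tc.total == T.total
        per_function = {}
        for (f, _), m in zip(tc.columns, tc.col_margins):
            per_function[f] = per_function.get(f, 0) + int(m)
        for f, m in zip(T.functions, T.col_margins):
            assert per_function[f] == int(m)

    def test_deterministic_under_seed(self, planted_dataset):
        G, T = planted_dataset.G_sim, planted_dataset.T_sim
        tc1, _ = gc.build_t_coexp(G, T, rng=np.random.default_rng(7))
        tc2, _ = gc.build_t_coexp(G, T, rng=np.random.default_rng(7))
        assert tc1.columns == tc2.columns
        assert np.array_equal(tc1.values, tc2.values)

    def test_alpha0_one_keeps_every_function_whole(self, planted_dataset):
        G, T = planted_dataset.G_sim, planted_dataset.T_sim
        tc, parts = gc.build_t_coexp(G, T, alpha0=1.0, rng=np.random.default_rng(0))
        assert all(p.coexpressed_whole for p in parts)
        assert np.array_equal(tc.values, T.values)

    def test_mismatched_universe_rejected(self, planted_dataset, toy_annotation):
        with pytest.raises(ValueError):
            gc.build_t_coexp(planted_dataset.G_sim, toy_annotation)

    def test_sub_clusters_ordered_by_decreasing_size(self, planted_dataset):
        G, T = planted_dataset.G_sim, planted_dataset.T_sim
        _, parts = gc.build_t_coexp(G, T, rng=np.random.default_rng(0))
        for p in parts:
            sizes = [len(c) for c in p.sub_clusters]
            assert sizes == sorted(sizes, reverse=True)


class TestDataclassInvariants:
    def test_function_partition_disjointness(self):
        with pytest.raises(ValueError):
            FunctionPartition("f", [["a", "b"], ["b"]], False)

    def test_whole_implies_single_subcluster(self):
        with pytest.raises(ValueError):
            FunctionPartition("f", [["a"], ["b"]], True)

    def test_coexp_matrix_rejects_margin_tampering(self, toy_annotation):
        tc = CoexpAnnotationMatrix.from_annotation(toy_annotation)
        with pytest.raises(ValueError):
            CoexpAnnotationMatrix(
                tc.genes, tc.columns, tc.values, col_margins=tc.col_margins + 1
            )
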