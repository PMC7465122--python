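"""Co-expression network construction, module detection and connectivity."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, strategies as st

from coexffl import gcn

from oracles import tom_oracle


def expr_frame(rows: dict[str, list[float]]) -> pd.DataFrame:
    return pd.DataFrame(rows).T


def factor_expression(
    sizes, loadings, n_samples=100, noise=0.3, seed=0, factor_cor=None
) -> tuple[pd.DataFrame, list[str]]:
    """Latent-factor expression with one factor per block.

    ``factor_cor`` optionally gives a common correlation between the block
    factors (used to test eigengene merging).
    """
    rng = np.random.default_rng(seed)
    k = len(sizes)
    if factor_cor is None:
        f = rng.standard_normal((k, n_samples))
    else:
        shared = rng.standard_normal(n_samples)
        f = np.array([
            np.sqrt(factor_cor) * shared + np.sqrt(1 - factor_cor) * rng.standard_normal(n_samples)
            for _ in range(k)
        ])
    rows, labels = [], []
    for b, (sz, l) in enumerate(zip(sizes, loadings)):
        for i in range(sz):
            rows.append(l * f[b] + rng.normal(0, noise, n_samples))
            labels.append(f"b{b}")
    genes = [f"g{i:03d}" for i in range(len(rows))]
    return pd.DataFrame(rows, index=genes), labels


class TestSimilarity:
    def test_duplicated_and_anticorrelated_genes(self):
        x = [1.0, 2.0, 3.0, 4.0]
        expr = expr_frame({"a": x, "b": x, "c": [-v for v in x]})
        S = gcn.similarity_matrix(expr)
        assert S.loc["a", "b"] == pytest.approx(1.0)
        assert S.loc["a", "c"] == pytest.approx(1.0)  # absolute correlation

    def test_hand_computed_three_genes(self):
        expr = expr_frame({"a": [1.0, 2.0, 3.0], "b": [1.0, 3.0, 2.0], "c": [2.0, 2.0, 5.0]})
        S = gcn.similarity_matrix(expr)
        ref = np.abs(np.corrcoef(expr.to_numpy()))
        np.testing.assert_allclose(S.to_numpy(), ref, atol=1e-12)

    def test_zero_variance_raises(self):
        expr = expr_frame({"a": [1.0, 1.0, 1.0], "b": [1.0, 2.0, 3.0]})
        with pytest.raises(ValueError):
            gcn.similarity_matrix(expr)


class TestScaleFreeFit:
    def test_exact_power_law_scores_high(self):
        # inverse-CDF sample from a Pareto degree distribution
        u = (np.arange(3000) + 0.5) / 3000
        k = u ** (-1.0 / 1.5)
        r2, slope = gcn.scale_free_fit(k)
        assert slope < 0
        assert r2 > 0.9

    def test_constant_connectivity_raises(self):
        with pytest.raises(ValueError):
            gcn.scale_free_fit(np.ones(100))

    def test_unreachable_target_falls_back_with_flag(self):
        expr, _ = factor_expression([20, 20], [0.9, 0.9], seed=1)
        S = gcn.similarity_matrix(expr)
        with pytest.warns(UserWarning):
            st_res = gcn.pick_soft_threshold(S, target_r2=0.99, n_samples=100)
        assert not st_res.reached_target
        assert 1 <= st_res.beta <= 20


class TestTOM:
    def test_unit_triangle(self):
        a = np.ones((3, 3)) - np.eye(3)
        om = gcn.tom_matrix(pd.DataFrame(a, index=list("abc"), columns=list("abc")))
        np.testing.assert_allclose(om.to_numpy(), np.ones((3, 3)))

    def test_isolated_pair(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = 0.5
        om = gcn.tom_matrix(pd.DataFrame(a, index=list("abc"), columns=list("abc")))
        assert om.iloc[0, 1] == pytest.approx(0.5)  # (0 + 0.5) / (0.5 + 1 - 0.5)
        assert om.iloc[0, 2] == pytest.approx(0.0)

    def test_empty_graph(self):
        om = gcn.tom_matrix(pd.DataFrame(np.zeros((4, 4))))
        assert np.allclose(om.to_numpy() - np.eye(4), 0.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        n = rng.integers(3, 12)
        a = rng.uniform(0, 1, (n, n))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 0.0)
        om = gcn.tom_matrix(pd.DataFrame(a))
        np.testing.assert_allclose(om.to_numpy(), tom_oracle(a), atol=1e-12)

    def test_negative_entries_rejected(self):
        a = np.zeros((3, 3))
        a[0, 1] = a[1, 0] = -0.1
        with pytest.raises(ValueError):
            gcn.tom_matrix(pd.DataFrame(a))


class TestAdjacencyMonotonicity:
    @given(st.integers(min_value=0, max_value=10_000))
    def test_raising_beta_never_increases_weights(self, seed):
        rng = np.random.default_rng(seed)
        s = rng.uniform(0, 1, (6, 6))
        s = (s + s.T) / 2
        np.fill_diagonal(s, 1.0)
        S = pd.DataFrame(s)
        prev = gcn.adjacency_matrix(S, 1).to_numpy()
        for beta in (2, 3, 5, 8):
            cur = gcn.adjacency_matrix(S, beta).to_numpy()
            assert (cur <= prev + 1e-12).all()
            prev = cur


class TestClusterAndCut:
    def test_two_planted_blocks_recovered_exactly(self):
        from sklearn.metrics import adjusted_rand_score

        expr, labels = factor_expression([40, 40], [0.9, 0.9], noise=0.3, seed=3)
        model = gcn.build_coexpression_network(expr, beta=6, min_module_size=30)
        found = model.partition.labels
        assert len(model.partition.modules) == 2
        assert adjusted_rand_score(labels, found.to_numpy()) == pytest.approx(1.0)

    def test_identical_genes_single_module(self):
        base = np.sin(np.arange(50))
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(
            [base + rng.normal(0, 1e-6, 50) for _ in range(35)],
            index=[f"g{i}" for i in range(35)],
        )
        S = gcn.similarity_matrix(expr)
        part = gcn.cluster_and_cut(1.0 - gcn.tom_matrix(gcn.adjacency_matrix(S, 6)))
        assert len(part.modules) == 1
        assert (part.labels != gcn.GREY).all()

    def test_too_few_genes_all_grey(self):
        expr, _ = factor_expression([10], [0.9], seed=1)
        S = gcn.similarity_matrix(expr)
        with pytest.warns(UserWarning):
            part = gcn.cluster_and_cut(1.0 - S, min_module_size=30)
        assert (part.labels == gcn.GREY).all()


class TestEigengenes:
    def test_identical_profiles_perfectly_represented(self):
        expr, _ = factor_expression([5], [0.9], noise=1e-8, seed=2, n_samples=30)
        part = gcn.ModulePartition(
            pd.Series("turquoise", index=expr.index), np.zeros((0, 4))
        )
        ME = gcn.module_eigengenes(expr, part)
        c = np.corrcoef(ME.loc["turquoise"], expr.iloc[0])[0, 1]
        assert abs(c) == pytest.approx(1.0, abs=1e-6)

    def test_sign_flip_leaves_abs_kme_unchanged(self):
        expr, _ = factor_expression([6], [0.9], seed=4, n_samples=40)
        part = gcn.ModulePartition(pd.Series("blue", index=expr.index), np.zeros((0, 4)))
        ME1 = gcn.module_eigengenes(expr, part)
        ME2 = gcn.module_eigengenes(-expr, part)
        k1 = np.corrcoef(np.vstack([expr.to_numpy(), ME1.to_numpy()]))[:-1, -1]
        k2 = np.corrcoef(np.vstack([(-expr).to_numpy(), ME2.to_numpy()]))[:-1, -1]
        np.testing.assert_allclose(np.abs(k1), np.abs(k2), atol=1e-10)

    def test_recovers_planted_factor(self):
        rng = np.random.default_rng(5)
        f = rng.standard_normal(120)
        expr = pd.DataFrame(
            [0.9 * f + rng.normal(0, 0.4, 120) for _ in range(30)],
            index=[f"g{i}" for i in range(30)],
        )
        part = gcn.ModulePartition(pd.Series("brown", index=expr.index), np.zeros((0, 4)))
        ME = gcn.module_eigengenes(expr, part)
        assert abs(np.corrcoef(ME.loc["brown"], f)[0, 1]) > 0.95

    def test_singleton_module_rejected(self):
        expr, _ = factor_expression([2], [0.9], seed=0, n_samples=10)
        labels = pd.Series(["blue", "turquoise"], index=expr.index)
        part = gcn.ModulePartition(labels, np.zeros((0, 4)))
        with pytest.raises(ValueError):
            gcn.module_eigengenes(expr, part)


class TestMergeCloseModules:
    def _partition(self, expr, labels):
        return gcn.ModulePartition(pd.Series(labels, index=expr.index), np.zeros((0, 4)))

    def test_highly_correlated_modules_merge(self):
        expr, _ = factor_expression([20, 20], [0.9, 0.9], factor_cor=0.95, noise=0.1, seed=6)
        part = self._partition(expr, ["turquoise"] * 20 + ["blue"] * 20)
        merged, _ = gcn.merge_close_modules(expr, part, merge_height=0.2)
        assert len(merged.modules) == 1
        assert merged.modules[0] == "turquoise"  # larger/equal module label survives

    def test_distinct_modules_stay_separate(self):
        expr, _ = factor_expression([20, 20], [0.9, 0.9], factor_cor=0.3, noise=0.1, seed=7)
        part = self._partition(expr, ["turquoise"] * 20 + ["blue"] * 20)
        merged, _ = gcn.merge_close_modules(expr, part, merge_height=0.2)
        assert len(merged.modules) == 2

    def test_three_modules_collapse_iteratively(self):
        expr, _ = factor_expression(
            [15, 15, 15], [0.9, 0.9, 0.9], factor_cor=0.97, noise=0.05, seed=8
        )
        part = self._partition(expr, ["turquoise"] * 15 + ["blue"] * 15 + ["brown"] * 15)
        merged, _ = gcn.merge_close_modules(expr, part, merge_height=0.2)
        assert len(merged.modules) == 1


class TestConnectivity:
    def _model(self, expr, labels):
        S = gcn.similarity_matrix(expr)
        A = gcn.adjacency_matrix(S, 6)
        Om = gcn.tom_matrix(A)
        part = gcn.ModulePartition(pd.Series(labels, index=expr.index), np.zeros((0, 4)))
        ME = gcn.module_eigengenes(expr, part)
        return gcn.connectivity_table(A, Om, expr, part, ME)

    def test_unit_weight_complete_module(self):
        x = np.linspace(0, 1, 20)
        expr = pd.DataFrame([2 * x, 2 * x + 1, 2 * x - 0.5, 3 * x], index=list("abcd"))
        table, _ = self._model(expr, ["turquoise"] * 4)
        np.testing.assert_allclose(table["k.in"], 3.0, atol=1e-9)

    def test_connectivity_identity_and_bruteforce(self):
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(rng.standard_normal((8, 60)), index=[f"g{i}" for i in range(8)])
        expr.iloc[:4] += 2.0 * rng.standard_normal(60)  # correlated block
        labels = ["turquoise"] * 4 + ["blue"] * 4
        S = gcn.similarity_matrix(expr)
        A = gcn.adjacency_matrix(S, 6)
        Om = gcn.tom_matrix(A)
        part = gcn.ModulePartition(pd.Series(labels, index=expr.index), np.zeros((0, 4)))
        ME = gcn.module_eigengenes(expr, part)
        table, _ = gcn.connectivity_table(A, Om, expr, part, ME, kme_floor=0.0)
        np.testing.assert_allclose(
            table["kTotal"], table["k.in"] + table["kOut"], atol=1e-12
        )
        a = A.to_numpy()
        for i, g in enumerate(expr.index):
            same = [j for j, l in enumerate(labels) if l == labels[i] and j != i]
            assert table.loc[g, "k.in"] == pytest.approx(sum(a[i, j] for j in same), abs=1e-12)
            assert table.loc[g, "kTotal"] == pytest.approx(
                sum(a[i, j] for j in range(8) if j != i), abs=1e-12
            )

    def test_gene_equal_to_eigengene_has_unit_mm(self):
        expr, _ = factor_expression([10], [0.9], noise=1e-9, seed=10, n_samples=50)
        table, _ = self._model(expr, ["turquoise"] * 10)
        assert table["MM"].iloc[0] == pytest.approx(1.0, abs=1e-5)

    def test_weakly_correlated_gene_reassigned_grey(self):
        expr, _ = factor_expression([10], [0.9], noise=0.2, seed=11, n_samples=80)
        rng = np.random.default_rng(12)
        expr.loc["noise"] = rng.standard_normal(expr.shape[1])
        table, part = self._model(expr, ["turquoise"] * 10 + ["turquoise"])
        assert part.labels["noise"] == gcn.GREY
        assert (part.labels.iloc[:10] == "turquoise").all()


class TestRepresentativeGenes:
    def test_strict_threshold(self):
        table = pd.DataFrame(
            {"module": ["blue", "blue", "grey"], "MM": [0.95, 0.9, 0.99]},
            index=["a", "b", "c"],
        )
        rep = gcn.representative_genes(table)
        assert rep == {"blue": ["a"]}  # 0.9 excluded (strict), grey excluded

    def test_high_loading_genes_selected(self):
        expr, _ = factor_expression([20], [0.98], noise=0.05, seed=13, n_samples=80)
        model = gcn.build_coexpression_network(expr, beta=6, min_module_size=10)
        rep = model.representative_genes_flat
        assert set(rep) == set(expr.index)


class TestPipelineDeterminism:
    def test_same_input_same_labels(self):
        expr, _ = factor_expression([35, 35], [0.9, 0.9], seed=14)
        m1 = gcn.build_coexpression_network(expr, beta=6)
        m2 = gcn.build_coexpression_network(expr, beta=6)
        pd.testing.assert_series_equal(m1.partition.labels, m2.partition.labels)
        pd.testing.assert_frame_equal(m1.eigengenes, m2.eigengenes)
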