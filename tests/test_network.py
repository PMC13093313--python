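import numpy as np
import pandas as pd
import pytest

from thermomem import network as nw
from tests.conftest import block_expression


def brute_force_tom(a: np.ndarray) -> np.ndarray:
    """Triple-loop TOM oracle (independent of the matrix implementation)."""
    n = a.shape[0]
    out = np.eye(n)
    k = a.sum(axis=1) - np.diag(a)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            l = sum(a[i, u] * a[u, j] for u in range(n) if u not in (i, j))
            out[i, j] = (l + a[i, j]) / (min(k[i], k[j]) + 1 - a[i, j])
    return out


class TestAdjacency:
    @pytest.mark.parametrize(
        "cor,expected", [(1.0, 1.0), (-1.0, 0.0), (0.0, 0.5**6)]
    )
    def test_closed_forms(self, cor, expected):
        x = np.linspace(-1, 1, 8)
        if cor == 1.0:
            y = 2 * x + 1
        elif cor == -1.0:
            y = -3 * x
        else:
            # orthogonal contrast has exactly zero correlation with x
            y = np.array([1, -1, 1, -1, 1, -1, 1, -1]) * np.std(x)
            y = y - np.polyfit(x, y, 1)[0] * x  # remove any linear component
        expr = pd.DataFrame([x, y], index=["a", "b"])
        adj = nw.signed_adjacency(expr, power=6)
        assert adj.loc["a", "b"] == pytest.approx(expected, abs=1e-10)
        assert adj.loc["a", "a"] == 1.0

    def test_bounds_symmetry_unit_diagonal(self):
        rng = np.random.default_rng(0)
        expr = pd.DataFrame(rng.standard_normal((30, 12)))
        a = nw.signed_adjacency(expr).to_numpy()
        assert ((a >= 0) & (a <= 1)).all()
        assert np.allclose(a, a.T)
        assert np.allclose(np.diag(a), 1.0)

    def test_zero_variance_gene_rejected(self):
        expr = pd.DataFrame([[1.0, 1.0, 1.0, 1.0], [0.0, 1.0, 2.0, 1.0]], index=["flat", "ok"])
        with pytest.raises(nw.NetworkInputError):
            nw.signed_adjacency(expr)


class TestTOM:
    def test_two_gene_closed_form(self):
        expr = pd.DataFrame(
            [[0.0, 1.0, 2.0, 4.0], [0.1, 0.9, 2.2, 3.7]], index=["a", "b"]
        )
        adj = nw.signed_adjacency(expr)
        tom = nw.tom_similarity(adj)
        assert tom.loc["a", "b"] == pytest.approx(adj.loc["a", "b"], abs=1e-12)

    def test_complete_unit_graph(self):
        adj = pd.DataFrame(np.ones((5, 5)), index=list("abcde"), columns=list("abcde"))
        tom = nw.tom_similarity(adj)
        assert np.allclose(tom.to_numpy(), 1.0)

    def test_matches_triple_loop_oracle(self):
        rng = np.random.default_rng(1)
        a = rng.uniform(0, 1, size=(6, 6))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        adj = pd.DataFrame(a, index=list("abcdef"), columns=list("abcdef"))
        tom = nw.tom_similarity(adj).to_numpy()
        oracle = brute_force_tom(a)
        assert np.abs(tom - oracle).max() < 1e-12

    def test_bounds(self):
        rng = np.random.default_rng(2)
        expr = pd.DataFrame(rng.standard_normal((40, 10)))
        tom = nw.tom_similarity(nw.signed_adjacency(expr)).to_numpy()
        assert ((tom >= 0) & (tom <= 1 + 1e-12)).all()
        assert np.allclose(tom, tom.T)


class TestModuleDetection:
    def test_two_planted_blocks_recovered(self):
        expr = block_expression([60, 60], [0.9, 0.9], n_samples=40, seed=3)
        tom = nw.tom_similarity(nw.signed_adjacency(expr))
        # no background genes here: the blocks occupy the whole tree, so the
        # cut must sit above block formation (only the final merge separates them)
        labels = nw.detect_modules(tom, nw.NetworkConfig(min_module_size=50, cut_quantile=0.995))
        planted = np.array([0] * 60 + [1] * 60)
        # exactly two modules, matching the blocks up to label permutation
        assert set(labels.unique()) == {1, 2}
        from sklearn.metrics import adjusted_rand_score

        assert adjusted_rand_score(planted, labels.to_numpy()) == 1.0

    def test_min_size_larger_than_n_genes_gives_background(self):
        expr = block_expression([30], [0.9], n_samples=20, seed=4, n_noise=10)
        tom = nw.tom_similarity(nw.signed_adjacency(expr))
        labels = nw.detect_modules(tom, nw.NetworkConfig(min_module_size=1000))
        assert (labels == 0).all()

    def test_small_block_absorbed_into_background(self):
        expr = block_expression([30], [0.9], n_samples=40, seed=5, n_noise=100)
        tom = nw.tom_similarity(nw.signed_adjacency(expr))
        # tight cut: the block forms its own 30-gene cluster, below min size
        labels = nw.detect_modules(tom, nw.NetworkConfig(min_module_size=50, cut_quantile=0.3))
        assert (labels.iloc[:30] == 0).all()

    def test_gene_order_invariance(self):
        expr = block_expression([55, 55], [0.85, 0.85], n_samples=30, seed=6, n_noise=20)
        tom = nw.tom_similarity(nw.signed_adjacency(expr))
        labels = nw.detect_modules(tom, nw.NetworkConfig(min_module_size=50))
        perm = np.random.default_rng(0).permutation(len(expr))
        expr_p = expr.iloc[perm]
        tom_p = nw.tom_similarity(nw.signed_adjacency(expr_p))
        labels_p = nw.detect_modules(tom_p, nw.NetworkConfig(min_module_size=50))
        from sklearn.metrics import adjusted_rand_score

        assert (
            adjusted_rand_score(labels.loc[expr_p.index].to_numpy(), labels_p.to_numpy())
            == 1.0
        )


class TestEigengene:
    def test_identical_genes_module(self):
        profile = np.array([0.0, 1.0, -1.0, 2.0, 0.5, -0.5])
        expr = pd.DataFrame([profile] * 4 + [profile * 3 + 1], index=[f"g{i}" for i in range(5)])
        labels = pd.Series(1, index=expr.index)
        me, kme = nw.module_eigengene(expr, labels)
        z = (profile - profile.mean()) / profile.std()
        assert np.allclose(np.abs(me.loc["ME1"].to_numpy()), np.abs(z), atol=1e-10)
        assert np.allclose(kme["ME1"].to_numpy(), 1.0, atol=1e-10)

    def test_matches_svd_oracle(self):
        rng = np.random.default_rng(7)
        expr = pd.DataFrame(rng.standard_normal((20, 15)))
        labels = pd.Series(1, index=expr.index)
        me, _ = nw.module_eigengene(expr, labels)
        z = (expr.to_numpy() - expr.to_numpy().mean(1, keepdims=True)) / expr.to_numpy().std(
            1, keepdims=True
        )
        _, _, vt = np.linalg.svd(z, full_matrices=False)
        oracle = vt[0] / vt[0].std()
        got = me.loc["ME1"].to_numpy()
        assert min(
            np.abs(got - oracle).max(), np.abs(got + oracle).max()
        ) < 1e-10

    def test_orientation_mean_kme_nonnegative(self):
        rng = np.random.default_rng(8)
        base = rng.standard_normal(12)
        expr = pd.DataFrame(
            [base + 0.1 * rng.standard_normal(12) for _ in range(6)],
            index=[f"g{i}" for i in range(6)],
        )
        labels = pd.Series(1, index=expr.index)
        me, kme = nw.module_eigengene(expr, labels)
        assert kme["ME1"].mean() > 0
        # unit variance convention
        assert me.loc["ME1"].std(ddof=0) == pytest.approx(1.0)

    def test_explains_most_member_variance(self):
        """The eigengene beats any random unit direction on explained variance."""
        rng = np.random.default_rng(9)
        expr = pd.DataFrame(rng.standard_normal((15, 10)))
        labels = pd.Series(1, index=expr.index)
        me, _ = nw.module_eigengene(expr, labels)
        z = (expr.to_numpy() - expr.to_numpy().mean(1, keepdims=True)) / expr.to_numpy().std(
            1, keepdims=True
        )
        h = me.loc["ME1"].to_numpy()
        h = h / np.linalg.norm(h)
        explained = np.sum((z @ h) ** 2)
        for _ in range(50):
            v = rng.standard_normal(10)
            v /= np.linalg.norm(v)
            assert np.sum((z @ v) ** 2) <= explained + 1e-9


class TestMerge:
    def _two_module_expr(self, factor_cor, seed=10):
        rng = np.random.default_rng(seed)
        n = 60
        f1 = rng.standard_normal(n)
        f2 = factor_cor * f1 + np.sqrt(1 - factor_cor**2) * rng.standard_normal(n)
        rows, ids = [], []
        for b, f in enumerate((f1, f2)):
            for i in range(20):
                rows.append(0.95 * f + 0.05 * rng.standard_normal(n))
                ids.append(f"b{b}_g{i}")
        expr = pd.DataFrame(rows, index=ids, columns=[f"s{j}" for j in range(n)])
        labels = pd.Series([1] * 20 + [2] * 20, index=ids)
        return expr, labels

    def test_highly_correlated_modules_merge(self):
        expr, labels = self._two_module_expr(0.95)
        merged = nw.merge_modules(expr, labels, merge_height=0.25)
        assert merged.nunique() == 1

    def test_moderately_correlated_modules_stay(self):
        expr, labels = self._two_module_expr(0.5)
        merged = nw.merge_modules(expr, labels, merge_height=0.25)
        assert merged.nunique() == 2

    def test_zero_merge_height_is_identity(self):
        expr, labels = self._two_module_expr(0.95)
        merged = nw.merge_modules(expr, labels, merge_height=1e-12)
        assert merged.nunique() == 2


class TestGeneSignificance:
    def test_gene_equal_to_trait_gives_one(self):
        trait = pd.Series([1.0, -1.0, 1.0, -1.0, 1.0], index=[f"s{i}" for i in range(5)])
        expr = pd.DataFrame([trait.to_numpy()], index=["g"], columns=trait.index)
        gs = nw.gene_significance(expr, trait)
        assert gs["g"] == pytest.approx(1.0)

    def test_independent_gene_small(self):
        rng = np.random.default_rng(11)
        n = 1000
        trait = pd.Series(rng.choice([-1.0, 1.0], n), index=[f"s{i}" for i in range(n)])
        expr = pd.DataFrame([rng.standard_normal(n)], index=["g"], columns=trait.index)
        assert nw.gene_significance(expr, trait)["g"] < 0.1

    def test_invariant_to_affine_trait_transform(self):
        rng = np.random.default_rng(12)
        trait = pd.Series(rng.standard_normal(20), index=[f"s{i}" for i in range(20)])
        expr = pd.DataFrame(rng.standard_normal((5, 20)), columns=trait.index)
        a = nw.gene_significance(expr, trait)
        b = nw.gene_significance(expr, 3.0 * trait - 7.0)
        assert np.allclose(a, b)

    def test_constant_trait_rejected(self):
        expr = pd.DataFrame(np.random.default_rng(0).standard_normal((3, 6)))
        with pytest.raises(nw.NetworkInputError):
            nw.gene_significance(expr, pd.Series(1.0, index=expr.columns))


class TestModuleTrait:
    def test_me_equal_to_coding_gives_rho_one(self):
        cols = [f"s{i}" for i in range(12)]
        coding = np.tile([-1.0, 1.0], 6)
        mes = pd.DataFrame([coding], index=["ME1"], columns=cols)
        traits = pd.DataFrame({"temperature": coding}, index=cols)
        table = nw.module_trait_correlation(mes, traits)
        row = table.iloc[0]
        assert row["rho"] == pytest.approx(1.0)
        assert row["p_value"] < 1e-4

    def test_exact_small_n_p_value(self):
        """n <= 9 uses exact enumeration: perfect rank agreement at n=5 has p = 2/5!."""
        cols = [f"s{i}" for i in range(5)]
        mes = pd.DataFrame([[1.0, 2.0, 3.0, 4.0, 5.0]], index=["ME1"], columns=cols)
        traits = pd.DataFrame({"weight": [0.1, 0.4, 0.9, 1.6, 2.5]}, index=cols)
        table = nw.module_trait_correlation(mes, traits)
        assert table.iloc[0]["p_value"] == pytest.approx(2.0 / 120.0)

    def test_symmetric_under_joint_sign_flip(self):
        rng = np.random.default_rng(13)
        cols = [f"s{i}" for i in range(14)]
        mes = pd.DataFrame([rng.standard_normal(14)], index=["ME1"], columns=cols)
        traits = pd.DataFrame({"weight": rng.standard_normal(14)}, index=cols)
        a = nw.module_trait_correlation(mes, traits).iloc[0]
        b = nw.module_trait_correlation(-mes, -traits).iloc[0]
        assert a["rho"] == pytest.approx(b["rho"])
        assert a["p_value"] == pytest.approx(b["p_value"])

    def test_planted_temperature_module_significant(self, small_sim, family_expression):
        """A module built around a temperature-responsive eigengene shows a
        significant module-trait correlation, as in the real analysis."""
        _, counts, design, truth = small_sim
        expr = family_expression["B"]
        net = nw.CoexpressionNetwork().fit(expr, design.loc[expr.columns])
        table = net.module_trait_
        # the detected module dominated by planted module 2 (temperature -2.0)
        lab = net.labels_
        overlap = {
            m: (truth.module_labels.loc[lab.index[lab == m]] == 2).sum()
            for m in set(lab.unique()) - {0}
        }
        det = max(overlap, key=overlap.get)
        row = table[(table["module"] == f"ME{det}") & (table["trait"] == "temperature")]
        assert row["p_value"].iloc[0] < 0.05
        assert row["rho"].iloc[0] < 0  # negative temperature response planted


class TestDegreeAndSoftThreshold:
    def test_complete_module_degree(self):
        n = 6
        adj = pd.DataFrame(np.ones((n, n)), index=list("abcdef"), columns=list("abcdef"))
        labels = pd.Series(1, index=adj.index)
        k = nw.weighted_degree(adj, labels, scope="intramodular")
        assert np.allclose(k, n - 1)

    def test_row_sum_oracle_and_background_zero(self):
        rng = np.random.default_rng(14)
        a = rng.uniform(0, 1, (8, 8))
        a = (a + a.T) / 2
        np.fill_diagonal(a, 1.0)
        ids = [f"g{i}" for i in range(8)]
        adj = pd.DataFrame(a, index=ids, columns=ids)
        labels = pd.Series([1, 1, 1, 1, 2, 2, 0, 0], index=ids)
        whole = nw.weighted_degree(adj, labels, scope="whole")
        oracle = a.sum(axis=1) - 1.0
        assert np.allclose(whole, oracle)
        intra = nw.weighted_degree(adj, labels, scope="intramodular")
        assert intra["g6"] == 0.0 and intra["g7"] == 0.0
        assert intra["g0"] == pytest.approx(a[0, 1:4].sum())

    def test_single_power_returned(self):
        rng = np.random.default_rng(15)
        expr = pd.DataFrame(rng.standard_normal((60, 12)))
        power, table = nw.pick_soft_threshold(expr, powers=(6,))
        assert power == 6 and len(table) == 1

    def test_duplicate_genes_leave_selection_unchanged(self):
        expr = block_expression([40, 40], [0.8, 0.8], n_samples=25, seed=16, n_noise=40)
        p1, _ = nw.pick_soft_threshold(expr, powers=(2, 4, 6), target_r2=0.8)
        dup = pd.concat([expr, expr.set_index(expr.index + "_dup")])
        p2, _ = nw.pick_soft_threshold(dup, powers=(2, 4, 6), target_r2=0.8)
        assert p1 == p2

    def test_fit_r2_matches_independent_rebinning(self):
        """Selected power's fit index agrees with an independent oracle that
        re-bins the connectivity distribution from scratch."""
        from scipy import stats as sps

        expr = block_expression(
            [30, 30, 30], [0.9, 0.7, 0.5], n_samples=30, seed=17, n_noise=60
        )
        power, table = nw.pick_soft_threshold(expr, powers=(6,), target_r2=0.0)
        # oracle
        cor = np.corrcoef(expr.to_numpy())
        adj = ((1 + cor) / 2) ** 6
        np.fill_diagonal(adj, 0)
        k = adj.sum(1)
        logk = np.log10(k)
        edges = np.linspace(logk.min(), logk.max() + 1e-12, 11)
        which = np.clip(np.digitize(logk, edges) - 1, 0, 9)
        xs = [np.log10(k[which == b].mean()) for b in range(10) if (which == b).any()]
        ys = [np.log10((which == b).mean()) for b in range(10) if (which == b).any()]
        slope, _, r, _, _ = sps.linregress(xs, ys)
        oracle_r2 = r * r * (-1 if slope > 0 else 1)
        assert table["fit_r2"].iloc[0] == pytest.approx(oracle_r2, abs=0.05)
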