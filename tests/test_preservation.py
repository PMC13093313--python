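import numpy as np
import pandas as pd
import pytest

from thermomem import preservation as pv
from tests.conftest import block_expression


def brute_force_statistics(disc, test, power=6):
    """Pairwise-loop oracle for the seven preservation statistics."""
    import math

    def cor(x, y):
        xm, ym = x - x.mean(), y - y.mean()
        return float(xm @ ym / math.sqrt((xm @ xm) * (ym @ ym)))

    def standardize(m):
        return (m - m.mean(1, keepdims=True)) / m.std(1, keepdims=True)

    def pc1(z):
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        h = vt[0]
        nc = np.array([cor(z[i], h) for i in range(z.shape[0])])
        if nc.mean() < 0:
            h, nc = -h, -nc
        return h, nc, s[0] ** 2 / (s**2).sum()

    dz, tz = standardize(np.asarray(disc, float)), standardize(np.asarray(test, float))
    m = dz.shape[0]
    cor_d = np.array([[cor(dz[i], dz[j]) for j in range(m)] for i in range(m)])
    cor_t = np.array([[cor(tz[i], tz[j]) for j in range(m)] for i in range(m)])
    adj_d = ((1 + cor_d) / 2) ** power
    adj_t = ((1 + cor_t) / 2) ** power
    np.fill_diagonal(adj_d, 0)
    np.fill_diagonal(adj_t, 0)
    _, nc_d, _ = pc1(dz)
    _, nc_t, coherence = pc1(tz)
    tril = [(i, j) for i in range(m) for j in range(i)]
    tril_d = np.array([cor_d[i, j] for i, j in tril])
    tril_t = np.array([cor_t[i, j] for i, j in tril])
    return {
        "avg_weight": float(np.mean([adj_t[i, j] for i, j in tril])),
        "coherence": float(coherence),
        "cor_cor": cor(tril_d, tril_t),
        "cor_degree": cor(adj_d.sum(1), adj_t.sum(1)),
        "cor_contrib": cor(nc_d, nc_t),
        "avg_cor": float(np.mean(tril_t * np.sign(tril_d))),
        "avg_contrib": float(np.mean(np.sign(nc_d) * nc_t)),
    }


def _paired_datasets(seed=0, n_genes=150, module=40, n=30, scramble=False):
    """Discovery/test expression pair with one planted module."""
    rng = np.random.default_rng(seed)
    ids = [f"g{i}" for i in range(n_genes)]
    lam = rng.uniform(0.5, 0.95, size=module)
    cols_d = [f"d{i}" for i in range(n)]
    cols_t = [f"t{i}" for i in range(n)]

    def build(scrambled):
        f = rng.standard_normal(n)
        rows = []
        for i in range(n_genes):
            if i < module and not scrambled:
                rows.append(lam[i] * f + np.sqrt(1 - lam[i] ** 2) * rng.standard_normal(n))
            else:
                rows.append(rng.standard_normal(n))
        return np.array(rows)

    disc = pd.DataFrame(build(False), index=ids, columns=cols_d)
    test = pd.DataFrame(build(scramble), index=ids, columns=cols_t)
    module_genes = ids[:module]
    return disc, test, module_genes


class TestObservedStatistics:
    def test_self_comparison_concordances_are_one(self):
        disc, _, genes = _paired_datasets(seed=1)
        stats, missing = pv.preservation_statistics(disc, disc, genes)
        assert missing == []
        assert stats["cor_cor"] == pytest.approx(1.0, abs=1e-12)
        assert stats["cor_degree"] == pytest.approx(1.0, abs=1e-12)
        assert stats["cor_contrib"] == pytest.approx(1.0, abs=1e-12)

    def test_noise_module_near_zero_cor_cor(self):
        disc, test, genes = _paired_datasets(seed=2, module=50, scramble=True)
        stats, _ = pv.preservation_statistics(disc, test, genes)
        assert abs(stats["cor_cor"]) < 0.2
        # coherence near the 1/min(n_genes, n_samples) baseline for noise
        assert stats["coherence"] < 3.0 / min(50, 30)

    def test_matches_pairwise_loop_oracle(self):
        rng = np.random.default_rng(3)
        ids = list("abcde")
        disc = pd.DataFrame(rng.standard_normal((5, 12)), index=ids)
        test = pd.DataFrame(rng.standard_normal((5, 12)), index=ids)
        stats, _ = pv.preservation_statistics(disc, test, ids)
        oracle = brute_force_statistics(disc.to_numpy(), test.to_numpy())
        for k, v in oracle.items():
            assert stats[k] == pytest.approx(v, abs=1e-10), k

    def test_size_and_coverage_errors(self):
        disc, test, genes = _paired_datasets(seed=4)
        with pytest.raises(pv.ModuleSizeError):
            pv.preservation_statistics(disc, test, genes[:2])
        test_small = test.drop(index=genes[: len(genes) // 2 + 1])
        with pytest.raises(pv.CoverageError):
            pv.preservation_statistics(disc, test_small, genes)

    def test_missing_genes_reported(self):
        disc, test, genes = _paired_datasets(seed=5)
        test_miss = test.drop(index=genes[:3])
        stats, missing = pv.preservation_statistics(disc, test_miss, genes)
        assert missing == genes[:3]


class TestPermutationTest:
    def test_planted_preserved_module_small_p(self):
        disc, test, genes = _paired_datasets(seed=6, scramble=False)
        cfg = pv.PreservationConfig(n_permutations=200, seed=0)
        res = pv.permutation_test(disc, test, genes, cfg)
        for s, p in res.p_values.items():
            assert p <= 0.01, s

    def test_scrambled_module_fails_concordance(self):
        disc, test, genes = _paired_datasets(seed=7, scramble=True)
        cfg = pv.PreservationConfig(n_permutations=200, seed=0)
        res = pv.permutation_test(disc, test, genes, cfg)
        assert res.p_values["cor_cor"] > 0.05
        # the same module in its own family is strongly self-preserved
        res_self = pv.permutation_test(disc, disc, genes, cfg)
        assert max(res_self.p_values.values()) <= 0.01

    def test_seeded_reproducibility(self):
        disc, test, genes = _paired_datasets(seed=8)
        cfg = pv.PreservationConfig(n_permutations=150, seed=42)
        p1 = pv.permutation_test(disc, test, genes, cfg).p_values
        p2 = pv.permutation_test(disc, test, genes, cfg).p_values
        assert p1 == p2

    def test_no_null_draw_beats_self_cor_cor(self):
        disc, _, genes = _paired_datasets(seed=9)
        cfg = pv.PreservationConfig(n_permutations=300, seed=1)
        res = pv.permutation_test(disc, disc, genes, cfg)
        # observed cor_cor is exactly 1; p must be the permutation floor
        assert res.observed["cor_cor"] == pytest.approx(1.0, abs=1e-12)
        assert res.p_values["cor_cor"] == pytest.approx(1.0 / 301.0)

    def test_insufficient_test_genes_error(self):
        disc, test, genes = _paired_datasets(seed=10, n_genes=60, module=40)
        with pytest.raises(pv.CoverageError):
            pv.permutation_test(disc, test, genes, pv.PreservationConfig(n_permutations=100))

    def test_monotone_power_in_loading_concordance(self):
        """Concordance statistics increase (weakly) with cross-dataset
        loading concordance, on a 3-point effect grid."""
        rng = np.random.default_rng(11)
        n, module, n_genes = 40, 30, 120
        ids = [f"g{i}" for i in range(n_genes)]
        lam = rng.uniform(0.4, 0.95, module)
        f_d = rng.standard_normal(n)
        disc_rows = [
            lam[i] * f_d + np.sqrt(1 - lam[i] ** 2) * rng.standard_normal(n)
            for i in range(module)
        ] + [rng.standard_normal(n) for _ in range(n_genes - module)]
        disc = pd.DataFrame(disc_rows, index=ids)
        values = []
        for w in (0.0, 0.5, 1.0):
            rng_t = np.random.default_rng(99)
            f_t = rng_t.standard_normal(n)
            lam_ind = rng_t.uniform(0.4, 0.95, module)
            lam_t = w * lam + (1 - w) * lam_ind
            rows = [
                lam_t[i] * f_t + np.sqrt(1 - lam_t[i] ** 2) * rng_t.standard_normal(n)
                for i in range(module)
            ] + [rng_t.standard_normal(n) for _ in range(n_genes - module)]
            test = pd.DataFrame(rows, index=ids)
            stats, _ = pv.preservation_statistics(disc, test, ids[:module])
            values.append((stats["cor_degree"], stats["cor_contrib"]))
        for k in range(2):
            seq = [v[k] for v in values]
            assert seq[0] <= seq[1] <= seq[2]


class TestClassification:
    def _result(self, pvals):
        return pv.PreservationResult(
            module=1, observed={k: 0.5 for k in pvals}, p_values=pvals, n_permutations=1000
        )

    def test_all_small_p_preserved(self):
        res = self._result({s: 1.0 / 1001 for s in pv.STATISTICS})
        out = pv.classify_preservation(res, alpha=0.01, rule="all")
        assert out.verdict == "preserved" and out.failing_statistics == []

    def test_one_failing_statistic_listed(self):
        pvals = {s: 1.0 / 1001 for s in pv.STATISTICS}
        pvals["coherence"] = 1.0
        out = pv.classify_preservation(self._result(pvals), alpha=0.01, rule="all")
        assert out.verdict == "not_preserved"
        assert out.failing_statistics == ["coherence"]

    def test_any_rule_flips_verdict(self):
        pvals = {s: 1.0 / 1001 for s in pv.STATISTICS}
        pvals["coherence"] = 1.0
        out = pv.classify_preservation(self._result(pvals), alpha=0.01, rule="any")
        assert out.verdict == "preserved"


class TestEstimator:
    def test_fit_on_planted_families(self, small_sim, family_expression):
        """Planted family-B modules: the scrambled one fails in family A,
        the others pass every statistic."""
        _, counts, design, truth = small_sim
        shared = family_expression["B"].index.intersection(family_expression["A"].index)
        labels = truth.module_labels.loc[shared]
        mp = pv.ModulePreservation(n_permutations=200, alpha=0.01, seed=0).fit(
            family_expression["B"], family_expression["A"], labels
        )
        assert set(mp.table_.columns) >= {"module", "statistic", "observed", "p_value"}
        scrambled = truth.nonpreserved_module
        assert mp.results_[scrambled].p_values["cor_cor"] > 0.05
        assert mp.results_[scrambled].verdict == "not_preserved"
        assert "cor_cor" in mp.results_[scrambled].failing_statistics
        for m, res in mp.results_.items():
            if m != scrambled:
                assert max(res.p_values.values()) <= 0.01
                assert res.verdict == "preserved"
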