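"""Differential-expression screens against independent oracles."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from preemiexpr.diffexpr import (
    bh_fdr,
    correlate_oxygen,
    exact_ranksum_p,
    lrt_adjusted,
    samseq_test,
    spearman_matrix,
)
from preemiexpr.matrix import CountMatrix, NormalizedMatrix


def make_norm(values, subjects=None):
    values = np.asarray(values, dtype=float)
    subjects = subjects or [f"s{j}" for j in range(values.shape[1])]
    df = pd.DataFrame(np.log2(values + 1.0),
                      index=[f"g{i}" for i in range(values.shape[0])],
                      columns=subjects)
    ones = pd.Series(1.0, index=subjects)
    return NormalizedMatrix(df, ones, ones)


class TestBhFdr:
    def brute_force(self, p):
        """Step-up oracle: q_i = min over j>=i of p_(j) * m / j."""
        p = np.asarray(p, float)
        m = len(p)
        order = np.argsort(p)
        q = np.empty(m)
        for rank_pos, idx in enumerate(order):
            candidates = [p[order[j]] * m / (j + 1) for j in range(rank_pos, m)]
            q[idx] = min(1.0, min(candidates))
        return q

    def test_five_value_fixture(self):
        p = [0.01, 0.02, 0.03, 0.04, 0.2]
        assert np.allclose(bh_fdr(p), [0.05, 0.05, 0.05, 0.05, 0.2])

    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_matches_brute_force_and_statsmodels(self, seed):
        rng = np.random.default_rng(seed)
        p = rng.random(23)
        q = bh_fdr(p)
        assert np.allclose(q, self.brute_force(p))
        from statsmodels.stats.multitest import multipletests
        assert np.allclose(q, multipletests(p, method="fdr_bh")[1])

    def test_edge_cases(self):
        assert bh_fdr([]).size == 0
        assert np.allclose(bh_fdr([1.0, 1.0, 1.0]), 1.0)
        assert bh_fdr([0.37])[0] == pytest.approx(0.37)

    def test_monotone_in_p_ranking(self):
        rng = np.random.default_rng(3)
        p = rng.random(50)
        q = bh_fdr(p)
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


class TestSpearman:
    def midrank_oracle(self, x, y):
        rx, ry = stats.rankdata(x), stats.rankdata(y)
        return np.corrcoef(rx, ry)[0, 1]

    def test_monotone_identity_and_reversal(self):
        x = np.array([[1.0, 2, 3, 4, 5]])
        rho, _ = spearman_matrix(np.exp(x), x[0])      # strictly increasing map
        assert rho[0] == pytest.approx(1.0)
        rho, _ = spearman_matrix(x, np.array([5.0, 4, 3, 2, 1]))
        assert rho[0] == pytest.approx(-1.0)

    def test_tie_fixture_matches_midrank_pearson_oracle(self):
        x = np.array([[3.0, 1, 4, 1, 5, 9]])  # tied pair
        y = np.array([2.0, 7, 1, 8, 2, 8])    # tied pairs in y too
        rho, _ = spearman_matrix(x, y)
        assert rho[0] == pytest.approx(self.midrank_oracle(x[0], y), abs=1e-12)

    @pytest.mark.parametrize("seed", [0, 5])
    def test_matches_scipy_on_random_data(self, seed):
        rng = np.random.default_rng(seed)
        X = rng.normal(size=(20, 15))
        y = rng.normal(size=15)
        rho, p = spearman_matrix(X, y)
        for g in range(20):
            r_sp, p_sp = stats.spearmanr(X[g], y)
            assert rho[g] == pytest.approx(r_sp, abs=1e-12)
            assert p[g] == pytest.approx(p_sp, abs=1e-9)


class TestExactRankSum:
    def test_complete_separation_5v5(self):
        assert exact_ranksum_p(0.0, 5, 5) == pytest.approx(2 / 252)
        assert exact_ranksum_p(25.0, 5, 5) == pytest.approx(2 / 252)

    @pytest.mark.parametrize("n1,n0", [(4, 5), (5, 5), (3, 8)])
    def test_matches_scipy_exact(self, n1, n0):
        rng = np.random.default_rng(1)
        for _ in range(5):
            x = rng.normal(size=n1)
            y = rng.normal(size=n0)
            u = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact")
            assert exact_ranksum_p(
                float(u.statistic), n1, n0) == pytest.approx(u.pvalue, abs=1e-12)


class TestCorrelateOxygen:
    def test_constant_auc_rejected(self, small_norm):
        auc = pd.Series(1.0, index=small_norm.subject_ids)
        with pytest.raises(ValueError, match="constant"):
            correlate_oxygen(small_norm, auc)

    def test_monotone_gene_tops_ranking(self):
        rng = np.random.default_rng(0)
        base = rng.integers(20, 200, size=(30, 20)).astype(float)
        auc = pd.Series(np.linspace(0, 3, 20), index=[f"s{j}" for j in range(20)])
        base[0] = 10 * np.arange(20) + 10      # strictly increasing in AUC
        norm = make_norm(base)
        res = correlate_oxygen(norm, auc)
        top = res.iloc[0]
        assert top["gene_id"] == "g0"
        assert top["statistic"] == pytest.approx(1.0)
        assert (res["direction"] == np.where(res["log2_fold_change"] >= 0,
                                             "up", "down")).all()


class TestSamSeq:
    def _counts(self, values):
        return CountMatrix(pd.DataFrame(
            values, index=[f"g{i}" for i in range(values.shape[0])],
            columns=[f"s{j}" for j in range(values.shape[1])]))

    def test_null_cohort_calls_nothing(self):
        rng = np.random.default_rng(10)
        counts = self._counts(rng.negative_binomial(10, 0.1, size=(300, 24)))
        group = np.arange(24) < 12
        res = samseq_test(counts, group, n_perms=100, seed=1)
        assert res["significant"].sum() <= 3  # ~1% of genes at most

    def test_depth_confound_neutralized(self):
        # identical distributions, 5x depth difference between groups: the
        # oracle is the same test on depth-equalized data, which calls nothing
        rng = np.random.default_rng(11)
        base = rng.negative_binomial(10, 0.1, size=(300, 24))
        confounded = base.copy()
        confounded[:, :12] = rng.poisson(base[:, :12] * 5.0)
        group = np.arange(24) < 12
        res_conf = samseq_test(self._counts(confounded), group, n_perms=100, seed=2)
        res_equal = samseq_test(self._counts(base), group, n_perms=100, seed=2)
        assert res_conf["significant"].sum() <= max(3, res_equal["significant"].sum() + 3)

    def test_planted_strong_gene_detected(self):
        rng = np.random.default_rng(12)
        values = rng.negative_binomial(10, 0.1, size=(200, 60))
        values[0, 30:] = rng.negative_binomial(40, 0.1, size=30)  # 4x shift
        group = np.arange(60) >= 30
        res = samseq_test(self._counts(values), group, n_perms=200, seed=3)
        row = res.set_index("gene_id").loc["g0"]
        assert bool(row["significant"])
        assert row["direction"] == "up"

    def test_subject_relabeling_invariance(self):
        rng = np.random.default_rng(13)
        values = rng.negative_binomial(10, 0.1, size=(50, 20))
        group = np.arange(20) < 10
        res1 = samseq_test(self._counts(values), group, n_perms=50, seed=4)
        perm = rng.permutation(20)
        res2 = samseq_test(self._counts(values[:, perm]), group[perm],
                           n_perms=50, seed=4)
        s1 = res1.set_index("gene_id")["statistic"]
        s2 = res2.set_index("gene_id")["statistic"]
        # same resampling seed, permuted subjects: statistics agree in
        # distribution; check the rank ordering of genes is highly conserved
        assert stats.spearmanr(s1, s2.loc[s1.index]).statistic > 0.95

    def test_degenerate_all_equal_counts_never_significant(self):
        values = np.full((20, 12), 50)
        res = samseq_test(self._counts(values), np.arange(12) < 6,
                          n_perms=50, seed=5)
        assert not res["significant"].any()
        assert np.allclose(res["statistic"], 0.0)


class TestLrtAdjusted:
    def irls_oracle(self, X, y, tol=1e-12):
        """Plain Newton-Raphson logistic fit, independent of the package path."""
        beta = np.zeros(X.shape[1])
        for _ in range(200):
            eta = X @ beta
            mu = 1.0 / (1.0 + np.exp(-eta))
            w = mu * (1.0 - mu)
            grad = X.T @ (y - mu)
            hess = X.T @ (X * w[:, None])
            step = np.linalg.solve(hess, grad)
            beta = beta + step
            if np.abs(step).max() < tol:
                break
        eta = X @ beta
        return (y * eta - np.log1p(np.exp(eta))).sum()

    def test_matches_irls_oracle_to_1e6(self):
        rng = np.random.default_rng(20)
        n = 40
        gab = rng.uniform(23, 30, n)
        gene = rng.normal(size=n)
        eta = -0.3 + 0.6 * gene - 0.2 * (gab - gab.mean())
        y = (rng.random(n) < 1 / (1 + np.exp(-eta))).astype(float)
        pre_log = np.exp2(np.vstack([gene, rng.normal(size=n)])) - 1 + 20
        norm = make_norm(pre_log)
        res = lrt_adjusted(norm, y, gab).set_index("gene_id")
        gab_std = (gab - gab.mean()) / gab.std()
        gene_std = (gene - gene.mean()) / gene.std()
        log2g = np.log2(pre_log[0] + 1)
        g_std = (log2g - log2g.mean()) / log2g.std()
        X0 = np.column_stack([np.ones(n), gab_std])
        X1 = np.column_stack([X0, g_std])
        expected = 2 * (self.irls_oracle(X1, y) - self.irls_oracle(X0, y))
        assert res.loc["g0", "statistic"] == pytest.approx(expected, abs=1e-6)

    def test_constant_gene_gives_zero_statistic(self):
        rng = np.random.default_rng(21)
        n = 30
        pre_log = np.vstack([np.full(n, 64.0), rng.integers(20, 200, n)])
        y = (rng.random(n) < 0.5).astype(float)
        gab = rng.uniform(23, 30, n)
        res = lrt_adjusted(make_norm(pre_log), y, gab).set_index("gene_id")
        assert res.loc["g0", "statistic"] == pytest.approx(0.0, abs=1e-8)
        assert res.loc["g0", "p_value"] == pytest.approx(1.0)

    def test_gene_collinear_with_gab_adds_nothing(self):
        rng = np.random.default_rng(22)
        n = 50
        gab = rng.uniform(23, 30, n)
        pre_log = np.vstack([np.exp2(gab / 3) - 1, rng.integers(20, 200, n)])
        y = (rng.random(n) < 1 / (1 + np.exp(-(gab - 26.5)))).astype(float)
        res = lrt_adjusted(make_norm(pre_log), y, gab).set_index("gene_id")
        assert res.loc["g0", "statistic"] == pytest.approx(0.0, abs=1e-4)

    def test_reduces_to_unadjusted_when_gab_constant(self):
        rng = np.random.default_rng(23)
        n = 40
        gene = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-gene))).astype(float)
        pre_log = np.exp2(np.vstack([gene + 5, rng.normal(size=n) + 5])) - 1
        norm = make_norm(pre_log)
        res_const = lrt_adjusted(norm, y, np.full(n, 28.0)).set_index("gene_id")
        # oracle: unadjusted LRT via statsmodels
        import statsmodels.api as sm
        log2g = norm.log2_values.to_numpy()[0]
        g_std = (log2g - log2g.mean()) / log2g.std()
        full = sm.Logit(y, sm.add_constant(g_std)).fit(disp=0)
        null = sm.Logit(y, np.ones((n, 1))).fit(disp=0)
        expected = 2 * (full.llf - null.llf)
        assert res_const.loc["g0", "statistic"] == pytest.approx(expected, abs=1e-5)
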