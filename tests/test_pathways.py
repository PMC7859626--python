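"""Gene-set handling, pathway eigengenes, and the forward-selection classifier."""

import numpy as np
import pandas as pd
import pytest

from preemiexpr.matrix import NormalizedMatrix
from preemiexpr.pathways import (
    GeneSetCollection,
    count_model_genes,
    count_table_genes,
    fit_pathway_classifier,
    forward_select,
    load_printed_prd_model,
    pathway_scores,
    read_gmt,
    screen_pathways,
    write_gmt,
)
from preemiexpr.spca import pc1_fit


def make_norm(log2_values, genes=None, subjects=None):
    log2_values = np.asarray(log2_values, dtype=float)
    genes = genes or [f"g{i}" for i in range(log2_values.shape[0])]
    subjects = subjects or [f"s{j}" for j in range(log2_values.shape[1])]
    df = pd.DataFrame(log2_values, index=genes, columns=subjects)
    ones = pd.Series(1.0, index=subjects)
    return NormalizedMatrix(df, ones, ones)


class TestGmt:
    def test_duplicate_members_deduplicated(self, tmp_path):
        path = tmp_path / "sets.gmt"
        path.write_text("P1\tdesc\tA\tB\tA\n")
        coll = read_gmt(path)
        assert coll.sets == {"P1": ["A", "B"]}

    def test_empty_file_warns(self, tmp_path):
        path = tmp_path / "empty.gmt"
        path.write_text("")
        with pytest.warns(UserWarning, match="empty"):
            coll = read_gmt(path)
        assert len(coll) == 0

    def test_malformed_line_reports_line_number(self, tmp_path):
        path = tmp_path / "bad.gmt"
        path.write_text("P1\tdesc\tA\nP2\tonly-two-fields\n")
        with pytest.raises(ValueError, match="line 2"):
            read_gmt(path)

    def test_round_trip_identity_on_canonical_form(self, tmp_path):
        coll = GeneSetCollection({"P1": ["A", "B"], "P2": ["C"]},
                                 descriptions={"P1": "x", "P2": "y"})
        path = tmp_path / "rt.gmt"
        write_gmt(coll, path)
        assert path.read_text() == "P1\tx\tA\tB\nP2\ty\tC\n"
        back = read_gmt(path)
        assert back.sets == coll.sets
        assert back.descriptions == coll.descriptions

    def test_bind_drops_absent_genes_with_warning(self):
        coll = GeneSetCollection({"P1": ["g0", "zzz"], "P2": ["zzz"]})
        with pytest.warns(UserWarning, match="dropped 2"):
            bound = coll.bind(["g0", "g1"])
        assert bound.sets == {"P1": ["g0"]}


class TestPathwayScores:
    def test_single_gene_pathway_is_standardized_gene(self):
        rng = np.random.default_rng(0)
        norm = make_norm(rng.normal(size=(3, 20)))
        scores, pcs = pathway_scores(norm, GeneSetCollection({"solo": ["g1"]}))
        gene = norm.log2_values.loc["g1"]
        standardized = (gene - gene.mean()) / gene.std(ddof=1)
        assert np.allclose(np.abs(scores.loc["solo"]), np.abs(standardized))

    def test_disjoint_pathways_independent_of_order(self):
        rng = np.random.default_rng(1)
        norm = make_norm(rng.normal(size=(8, 25)))
        a = GeneSetCollection({"P1": ["g0", "g1"], "P2": ["g4", "g5"]})
        b = GeneSetCollection({"P2": ["g4", "g5"], "P1": ["g0", "g1"]})
        sa, _ = pathway_scores(norm, a)
        sb, _ = pathway_scores(norm, b)
        assert np.allclose(sa.loc["P1"], sb.loc["P1"])
        assert np.allclose(sa.loc["P2"], sb.loc["P2"])

    def test_latent_factor_recovery_at_n500(self):
        # generator-truth oracle: pathway built from one latent factor at
        # r=0.8; its eigengene must track the factor almost perfectly
        rng = np.random.default_rng(2)
        n, g = 500, 20
        factor = rng.normal(size=n)
        rho = 0.8
        X = (np.sqrt(rho) * factor[None, :]
             + np.sqrt(1 - rho) * rng.normal(size=(g, n)))
        norm = make_norm(X)
        sets = GeneSetCollection({"block": [f"g{i}" for i in range(g)]})
        scores, _ = pathway_scores(norm, sets)
        r = np.corrcoef(scores.loc["block"], factor)[0, 1]
        assert abs(r) >= 0.9

    def test_shared_gene_contributes_to_each_pathway(self):
        rng = np.random.default_rng(3)
        norm = make_norm(rng.normal(size=(6, 30)))
        sets = GeneSetCollection({"P1": ["g0", "g1", "g2"], "P2": ["g2", "g3", "g4"]})
        _, pcs = pathway_scores(norm, sets)
        assert "g2" in pcs["P1"].loadings.index
        assert "g2" in pcs["P2"].loadings.index


class TestScreenPathways:
    def test_constant_score_excluded(self):
        rng = np.random.default_rng(4)
        scores = pd.DataFrame(np.vstack([np.zeros(30), rng.normal(size=30)]),
                              index=["flat", "varied"],
                              columns=[f"s{j}" for j in range(30)])
        y = rng.integers(0, 2, 30)
        y[:2] = [0, 1]
        res = screen_pathways(scores, y, alpha=0.5).set_index("pathway")
        assert res.loc["flat", "p_value"] == pytest.approx(1.0, abs=1e-6)
        assert not res.loc["flat", "survives"]

    def test_outcome_equal_score_dominates(self):
        rng = np.random.default_rng(5)
        y = np.array([0, 1] * 15)
        scores = pd.DataFrame(
            np.vstack([y.astype(float), rng.normal(size=30), rng.normal(size=30)]),
            index=["oracle", "n1", "n2"], columns=[f"s{j}" for j in range(30)])
        res = screen_pathways(scores, y, alpha=0.05)
        assert res.iloc[0]["pathway"] == "oracle"
        assert res.iloc[0]["penalized"]  # separation -> ridge fallback flagged

    def test_lrt_matches_statsmodels_oracle(self):
        import statsmodels.api as sm
        rng = np.random.default_rng(6)
        n = 60
        score = rng.normal(size=n)
        gab = rng.uniform(23, 35, n)
        y = (rng.random(n) < 1 / (1 + np.exp(-(0.8 * score)))).astype(float)
        scores = pd.DataFrame(score[None, :], index=["pw"],
                              columns=[f"s{j}" for j in range(n)])
        res = screen_pathways(scores, y, gab_weeks=gab, alpha=0.1)
        gab_std = (gab - gab.mean()) / gab.std()
        s_std = (score - score.mean()) / score.std()
        full = sm.Logit(y, np.column_stack([np.ones(n), gab_std, s_std])).fit(disp=0)
        null = sm.Logit(y, np.column_stack([np.ones(n), gab_std])).fit(disp=0)
        assert res["lrt_stat"][0] == pytest.approx(2 * (full.llf - null.llf), abs=1e-6)


class TestForwardSelection:
    def test_duplicated_pathway_never_chosen_second(self):
        rng = np.random.default_rng(7)
        n = 60
        signal = rng.normal(size=n)
        y = (rng.random(n) < 1 / (1 + np.exp(-2 * signal))).astype(int)
        scores = pd.DataFrame(
            np.vstack([signal, signal, rng.normal(size=n)]),
            index=["sig", "sig_copy", "indep"],
            columns=[f"s{j}" for j in range(n)])
        order = forward_select(scores, y, k_max=2)
        assert order[0] in ("sig", "sig_copy")
        assert order[1] == "indep"  # the exact copy adds zero likelihood

    def test_likelihood_gain_nonnegative_along_path(self):
        from preemiexpr._glm import fit_logistic
        rng = np.random.default_rng(8)
        n = 50
        scores = pd.DataFrame(rng.normal(size=(6, n)),
                              index=[f"p{i}" for i in range(6)],
                              columns=[f"s{j}" for j in range(n)])
        y = rng.integers(0, 2, n).astype(float)
        y[:2] = [0, 1]
        order = forward_select(scores, y, k_max=4)
        lls = []
        for k in range(1, 5):
            X = np.column_stack([np.ones(n)] + [scores.loc[p] for p in order[:k]])
            _, ll, _ = fit_logistic(X, y)
            lls.append(ll)
        assert all(b >= a - 1e-8 for a, b in zip(lls, lls[1:]))


class TestModelCounts:
    def test_printed_four_pathway_table_has_28_distinct_genes(self):
        table = load_printed_prd_model()
        assert len(table) == 29            # membership rows
        assert count_table_genes(table) == 28   # SLCO1A2 shared
        assert table["pathway"].nunique() == 4

    def test_empty_and_fully_overlapping_models(self):
        from preemiexpr.pathways import PathwayModel
        empty = PathwayModel([], {}, 0.0, pd.Series(dtype=float),
                             pd.Series(dtype=float), 0.1, "forward", 0)
        assert count_model_genes(empty) == 0
        dup = PathwayModel(["A", "B"], {}, 0.0, pd.Series(dtype=float),
                           pd.Series(dtype=float), 0.1, "forward", 0,
                           membership={"A": list("vwxyz"), "B": list("vwxyz")})
        assert count_model_genes(dup) == 5


class TestClassifier:
    @pytest.fixture(scope="class")
    def planted(self):
        from preemiexpr.preprocess import run_preprocess
        from preemiexpr.synthetic import SimulationConfig, simulate_cohort
        cfg = SimulationConfig(n_subjects=80, n_genes=400, n_pathways=25,
                               genes_per_pathway=(6, 10), pathway_overlap_prob=0.0,
                               frac_signal_genes=0.025, signal_log2fc=1.3,
                               signal_in_pathways=True, signal_outcome="prd",
                               prd_missing_rate=0.0, seed=17)
        cohort = simulate_cohort(cfg)
        norm = run_preprocess(cohort.counts)
        meta = cohort.metadata_frame().loc[norm.subject_ids]
        y = (meta["prd"] == "yes").to_numpy().astype(int)
        return cohort, norm, y

    def test_degenerate_grids_give_top_screen_pathway(self, planted):
        cohort, norm, y = planted
        model = fit_pathway_classifier(norm, cohort.gene_sets, y,
                                       alpha_grid=[1.0], k_grid=[1],
                                       cv_folds=4, seed=0)
        scores, _ = pathway_scores(norm, cohort.gene_sets)
        screen = screen_pathways(scores, y, alpha=1.0)
        assert model.selected_pathways == [screen.iloc[0]["pathway"]]

    def test_planted_pathway_selected_and_counted(self, planted):
        cohort, norm, y = planted
        model = fit_pathway_classifier(norm, cohort.gene_sets, y,
                                       alpha_grid=[0.05, 0.1], k_grid=[1, 2],
                                       cv_folds=4, seed=1)
        assert cohort.truth["signal_pathways"][0] in model.selected_pathways
        expected = len({g for m in model.membership.values() for g in m})
        assert count_model_genes(model) == expected
        table = model.to_table()
        assert count_table_genes(table) == expected
        assert set(table["pathway"]) == set(model.selected_pathways)

    def test_lasso_path_shrinks_to_intercept_only(self, planted):
        cohort, norm, y = planted
        model = fit_pathway_classifier(
            norm, cohort.gene_sets, y, alpha_grid=[0.5], k_grid=None,
            method="lasso", cv_folds=4,
            lasso_penalties=(1.0, 0.1, 0.0001), seed=2)
        # coefficient magnitudes shrink monotonically along the penalty path
        scores, _ = pathway_scores(norm, cohort.gene_sets)
        screen = screen_pathways(scores, y, alpha=0.5)
        surv = screen.loc[screen["survives"], "pathway"]
        from preemiexpr.pathways import _lasso_fit
        norms = [np.abs(_lasso_fit(scores.loc[surv], y, None, C).coef_).sum()
                 for C in (1.0, 0.1, 0.0001)]
        assert norms[0] >= norms[1] >= norms[2]
        assert norms[2] == pytest.approx(0.0, abs=1e-8)  # ~infinite penalty

    def test_reproducible_under_fixed_seed(self, planted):
        cohort, norm, y = planted
        kwargs = dict(alpha_grid=[0.05, 0.1], k_grid=[1, 2], cv_folds=4, seed=3)
        m1 = fit_pathway_classifier(norm, cohort.gene_sets, y, **kwargs)
        m2 = fit_pathway_classifier(norm, cohort.gene_sets, y, **kwargs)
        assert m1.selected_pathways == m2.selected_pathways
        pd.testing.assert_series_equal(m1.pathway_log_or, m2.pathway_log_or)
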