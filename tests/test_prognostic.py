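import numpy as np
import pandas as pd
import pytest
from scipy.optimize import minimize_scalar

from tiprog.containers import ExpressionMatrix, SurvivalCohort, ValidationError
from tiprog.prognostic import (
    RiskScoreModel,
    breslow_partial_loglik,
    de_test,
    evaluate_model,
    fit_risk_model,
    intersect_candidates,
    ipcw_time_auc,
    lasso_cox_select,
    score_signature_survival,
    stratify_by_median,
    univariate_cox_screen,
)
from tiprog.simulate import SurvSimConfig, simulate_bulk_survival


def make_cohort(expr, time, event, genes=None):
    genes = genes or [f"g{i}" for i in range(expr.shape[0])]
    samples = [f"s{j}" for j in range(expr.shape[1])]
    mat = ExpressionMatrix(genes, samples, np.asarray(expr, float), "lognorm")
    tab = pd.DataFrame({"sample_id": samples, "time": time, "event": event})
    return SurvivalCohort(mat, tab)


class TestDeTest:
    def make_mat(self, values):
        values = np.asarray(values, float)
        return ExpressionMatrix([f"g{i}" for i in range(values.shape[0])],
                                [f"c{j}" for j in range(values.shape[1])],
                                values, "lognorm")

    def test_identical_groups_null(self):
        rng = np.random.default_rng(0)
        vals = rng.exponential(1.0, (5, 6))
        mat = self.make_mat(np.hstack([vals, vals]))
        out = de_test(mat, [f"c{j}" for j in range(6)],
                      [f"c{j}" for j in range(6, 12)])
        np.testing.assert_allclose(out["log2fc"], 0.0, atol=1e-12)
        assert (out["p"] >= 0.9).all()

    def test_strong_separation_gene(self):
        from itertools import combinations
        from scipy.stats import mannwhitneyu
        vals = np.vstack([np.r_[np.full(5, 10.0), np.zeros(5)],
                          np.ones(10)])
        mat = self.make_mat(vals)
        out = de_test(mat, [f"c{j}" for j in range(5)],
                      [f"c{j}" for j in range(5, 10)]).set_index("gene_id")
        assert abs(out.loc["g0", "log2fc"]) > 1
        # enumeration over all 252 relabelings: the observed complete
        # separation attains the minimal p of the test statistic used
        x = vals[0]
        p_all = [mannwhitneyu(x[list(idx)],
                              x[[j for j in range(10) if j not in idx]],
                              alternative="two-sided").pvalue
                 for idx in combinations(range(10), 5)]
        assert out.loc["g0", "p"] == pytest.approx(min(p_all), rel=1e-9)

    def test_bh_adjustment_hand_case(self):
        # BH on (0.01, 0.02, 0.03, 0.04) gives 0.04 everywhere
        from statsmodels.stats.multitest import multipletests
        p_adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(p_adj, 0.04)

    def test_bh_recomputable_from_raw_p(self):
        rng = np.random.default_rng(1)
        mat = self.make_mat(rng.exponential(1.0, (20, 12)))
        out = de_test(mat, [f"c{j}" for j in range(6)],
                      [f"c{j}" for j in range(6, 12)])
        p = out["p"].to_numpy()
        n = len(p)
        order = np.argsort(p)
        stepped = np.minimum.accumulate((p[order] * n / np.arange(1, n + 1))[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(stepped, 1.0)
        np.testing.assert_allclose(out["p_adj"], expected)

    def test_small_group_rejected(self, toy_matrix):
        with pytest.raises(ValidationError):
            de_test(toy_matrix, ["c0"], ["c1", "c2"])


class TestIntersectCandidates:
    def table(self, rows):
        return pd.DataFrame(rows, columns=["gene_id", "log2fc", "p", "p_adj"])

    def test_disjoint_sets_empty(self):
        a = self.table([("g1", 2.0, 1e-4, 1e-3)])
        b = self.table([("g2", 2.0, 1e-4, 1e-3)])
        assert intersect_candidates(a, b) == []

    def test_identical_sets_all_kept(self):
        rows = [(f"g{i}", 1.5, 1e-4, 1e-3) for i in range(7)]
        out = intersect_candidates(self.table(rows), self.table(rows))
        assert len(out) == 7

    def test_partial_overlap_hand_intersection(self):
        a = self.table([("g1", 2.0, 1e-4, 1e-3), ("g2", 0.5, 1e-4, 1e-3),
                        ("g3", -3.0, 1e-4, 1e-3)])
        b = self.table([("g1", 1.5, 1e-4, 1e-3), ("g3", 2.0, 1e-4, 0.2),
                        ("g4", 2.0, 1e-4, 1e-3)])
        # g2 fails |log2fc|>1 in a; g3 fails p_adj in b -> only g1
        assert intersect_candidates(a, b) == ["g1"]


class TestUnivariateCox:
    def test_wald_p_matches_brute_force_partial_likelihood(self):
        # binary gene, distinct event times: compare with direct maximization
        rng = np.random.default_rng(2)
        n = 40
        x = np.r_[np.zeros(20), np.ones(20)]
        time = rng.exponential(1.0 / np.exp(0.8 * x))
        cohort = make_cohort(x[None, :], time, np.ones(n, int))
        out = univariate_cox_screen(cohort, ["g0"], p_threshold=1.1)
        z = (x - x.mean()) / x.std(ddof=1)
        res = minimize_scalar(lambda b: -breslow_partial_loglik(b * z, time, np.ones(n)))
        beta_hat = res.x
        eps = 1e-4
        d2 = (breslow_partial_loglik((beta_hat + eps) * z, time, np.ones(n))
              - 2 * breslow_partial_loglik(beta_hat * z, time, np.ones(n))
              + breslow_partial_loglik((beta_hat - eps) * z, time, np.ones(n))) / eps ** 2
        se = 1.0 / np.sqrt(-d2)
        from scipy.stats import norm
        p_expected = 2 * norm.sf(abs(beta_hat / se))
        assert out.loc[0, "coef"] == pytest.approx(beta_hat, abs=1e-4)
        assert out.loc[0, "p"] == pytest.approx(p_expected, rel=1e-3)

    def test_null_retention_near_five_percent(self):
        _, cohort, _ = simulate_bulk_survival(
            SurvSimConfig(n_samples=300, n_genes=100, seed=3))
        kept = univariate_cox_screen(cohort, list(cohort.expression.gene_ids))
        # binomial(100, 0.05): central 99% range roughly [0, 12]
        assert len(kept) <= 12

    def test_planted_gene_retained_with_positive_hr(self):
        retained = 0
        for r in range(10):
            _, cohort, _ = simulate_bulk_survival(SurvSimConfig(
                n_samples=300, n_genes=5, causal_genes=[("G00000", 1.0)],
                seed=50 + r))
            out = univariate_cox_screen(cohort, ["G00000"])
            if len(out) and out.loc[0, "hr"] > 1:
                retained += 1
        assert retained >= 9


class TestLassoCox:
    def test_recovers_strong_gene_among_nulls(self):
        _, cohort, _ = simulate_bulk_survival(SurvSimConfig(
            n_samples=400, n_genes=51, causal_genes=[("G00010", 1.0)], seed=4))
        selected, lam, cv = lasso_cox_select(
            cohort, list(cohort.expression.gene_ids), seed=5)
        assert "G00010" in selected
        assert lam > 0
        assert (np.diff(cv["alpha"]) < 0).all() or (np.diff(cv["alpha"]) > 0).all()

    def test_duplicated_gene_column_selects_at_most_one_extra(self):
        # L1 grouping on identical columns: the pair carries one signal
        bulk, cohort, _ = simulate_bulk_survival(SurvSimConfig(
            n_samples=300, n_genes=20, causal_genes=[("G00000", 1.0)], seed=6))
        vals = np.vstack([bulk.values, bulk.values[0:1, :]])
        genes = list(bulk.gene_ids) + ["G00000_copy"]
        dup = make_cohort(vals, cohort.time, cohort.event, genes=genes)
        selected, _, _ = lasso_cox_select(dup, genes, seed=7)
        assert {"G00000", "G00000_copy"} & set(selected)

    def test_too_few_candidates_rejected(self, surv_cohort):
        _, cohort, _ = surv_cohort
        with pytest.raises(ValidationError):
            lasso_cox_select(cohort, ["G00000"])


class TestRiskModel:
    def test_hand_computed_scores_and_median_tie_rule(self):
        scores = pd.Series([0.7, 1.4, 2.1], index=["a", "b", "c"])
        groups = stratify_by_median(scores)
        # median 1.4; only the strictly greater score is high risk
        assert groups.tolist() == ["low", "low", "high"]

    def test_median_split_balanced_for_distinct_scores(self):
        rng = np.random.default_rng(8)
        for n in (10, 11, 50):
            scores = pd.Series(rng.normal(0, 1, n))
            groups = stratify_by_median(scores)
            assert abs((groups == "high").sum() - (groups == "low").sum()) <= 1

    def test_sample_order_permutation_keeps_assignments(self, surv_cohort):
        bulk, cohort, truth = surv_cohort
        genes = sorted(truth.causal_betas)[:4]
        m = fit_risk_model(cohort, genes)
        rng = np.random.default_rng(9)
        perm = rng.permutation(bulk.n_obs)
        cohort2 = SurvivalCohort(bulk.subset_obs(perm),
                                 cohort.table.iloc[perm].reset_index(drop=True))
        m2 = fit_risk_model(cohort2, genes)
        pd.testing.assert_series_equal(m.groups_.sort_index(), m2.groups_.sort_index())

    def test_end_to_end_recovery(self, surv_cohort):
        bulk, cohort, truth = surv_cohort
        model = RiskScoreModel(seed=3).fit(cohort)
        recovered = set(model.genes_) & set(truth.causal_betas)
        assert len(recovered) >= 7
        ev = evaluate_model(model.scores_, cohort)
        assert ev.hr > 1 and ev.hr_p < 0.001
        assert ev.hr_ci[0] <= ev.hr <= ev.hr_ci[1]

    def test_predict_matches_training_scores(self, surv_cohort):
        bulk, cohort, _ = surv_cohort
        model = RiskScoreModel(seed=3).fit(cohort)
        pred = model.predict(bulk)
        np.testing.assert_allclose(pred.to_numpy(), model.scores_.to_numpy())

    def test_adjusted_hr_with_covariate(self, surv_cohort):
        bulk, cohort, _ = surv_cohort
        rng = np.random.default_rng(10)
        tab = cohort.table.copy()
        tab["age"] = rng.uniform(40, 80, len(tab))
        cohort2 = SurvivalCohort(bulk, tab)
        model = RiskScoreModel(seed=3).fit(cohort2)
        ev = evaluate_model(model.scores_, cohort2, covariates=["age"])
        assert ev.hr_adjusted is not None and ev.hr_adjusted > 1


class TestTimeDependentAuc:
    def test_constant_score_gives_exactly_half(self, surv_cohort):
        _, cohort, _ = surv_cohort
        auc = ipcw_time_auc(cohort.time, cohort.event, np.full(300, 2.0))
        assert all(v == 0.5 for v in auc.values())

    def test_true_log_hazard_discriminates(self):
        causal = [(f"G0000{i}", 1.0) for i in range(5)]
        bulk, cohort, _ = simulate_bulk_survival(SurvSimConfig(
            n_samples=300, n_genes=10, causal_genes=causal, seed=11))
        z = (bulk.values - bulk.values.mean(axis=1, keepdims=True)) \
            / bulk.values.std(axis=1, ddof=1, keepdims=True)
        lp = z[:5].sum(axis=0)
        auc = ipcw_time_auc(cohort.time, cohort.event, lp)
        assert all(v >= 0.8 for v in auc.values())

    def test_agrees_with_sksurv_estimator(self):
        # independent cross-check against the IPCW estimator in scikit-survival
        from sksurv.metrics import cumulative_dynamic_auc
        from sksurv.util import Surv
        rng = np.random.default_rng(12)
        _, cohort, _ = simulate_bulk_survival(SurvSimConfig(
            n_samples=200, n_genes=3, causal_genes=[("G00000", 0.8)], seed=13))
        score = cohort.expression.values[0] + rng.normal(0, 0.1, 200)
        horizons = (12.0, 24.0, 36.0)
        mine = ipcw_time_auc(cohort.time, cohort.event, score, horizons)
        y = Surv.from_arrays(cohort.event.astype(bool), cohort.time)
        theirs, _ = cumulative_dynamic_auc(y, y, score, list(horizons))
        np.testing.assert_allclose([mine[h] for h in horizons], theirs, atol=1e-8)


class TestSignatureSurvival:
    def test_planted_signature_separates_survival(self):
        rng = np.random.default_rng(14)
        causal = [(f"G{i:05d}", 1.0) for i in rng.choice(50, 5, replace=False)]
        bulk, cohort, _ = simulate_bulk_survival(SurvSimConfig(
            n_samples=300, n_genes=50, causal_genes=causal, seed=15))
        out = score_signature_survival(bulk, cohort, [g for g, _ in causal])
        assert out["logrank_p"] < 0.01

    def test_null_logrank_p_uniform(self):
        from scipy.stats import kstest
        from lifelines.statistics import logrank_test
        ps = []
        for r in range(100):
            _, cohort, _ = simulate_bulk_survival(SurvSimConfig(
                n_samples=60, n_genes=3, seed=20_000 + r))
            g = stratify_by_median(pd.Series(cohort.expression.values[0],
                                             index=cohort.expression.obs_ids))
            hi = (g == "high").to_numpy()
            ps.append(logrank_test(cohort.time[hi], cohort.time[~hi],
                                   cohort.event[hi], cohort.event[~hi]).p_value)
        assert kstest(ps, "uniform").pvalue > 0.01

    def test_single_sample_rejected(self):
        mat = ExpressionMatrix(["g0"], ["s0"], [[1.0]], "lognorm")
        tab = pd.DataFrame({"sample_id": ["s0"], "time": [5.0], "event": [1]})
        cohort = SurvivalCohort(mat, tab)
        with pytest.raises(ValidationError):
            score_signature_survival(mat, cohort, ["g0"])

    def test_unmatched_signature_rejected(self, surv_cohort):
        bulk, cohort, _ = surv_cohort
        with pytest.raises(ValidationError):
            score_signature_survival(bulk, cohort, ["absent_gene"])
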