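"""Gene-signature survival risk models.

The chain mirrors the construction of dual prognostic models from
tumor/immune differential expression: DE candidates are intersected,
screened by univariate Cox regression (p < 0.05), reduced by an
L1-penalized Cox path with the penalty chosen at minimum cross-validated
partial-likelihood deviance, and combined into a risk score
``sum_i beta_i x_i`` from the multivariate Cox coefficients.  Patients are
stratified at the median score and the stratification is evaluated with
Kaplan-Meier/log-rank statistics, IPCW time-dependent AUC at 2/4/6/8-year
horizons, and Cox hazard ratios of the continuous score with and without
covariate adjustment.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from sklearn.base import BaseEstimator
from sklearn.model_selection import StratifiedKFold
from sksurv.linear_model import CoxnetSurvivalAnalysis
from sksurv.util import Surv
from statsmodels.stats.multitest import multipletests

from .containers import ExpressionMatrix, SurvivalCohort, ValidationError

logger = logging.getLogger(__name__)

DEFAULT_HORIZONS = (24.0, 48.0, 72.0, 96.0)  # months: 2, 4, 6, 8 years


# ---------------------------------------------------------------------------
# differential expression and candidate intersection
# ---------------------------------------------------------------------------

def de_test(mat: ExpressionMatrix, group_a: list[str], group_b: list[str],
            pseudocount: float = 1.0) -> pd.DataFrame:
    """Two-sided Wilcoxon rank-sum DE between two cell groups.

    log2FC = log2(mean_a + pc) - log2(mean_b + pc) on the normalized scale;
    p values are Benjamini-Hochberg adjusted across all tested genes.
    """
    from scipy.stats import mannwhitneyu

    if len(group_a) < 3 or len(group_b) < 3:
        raise ValidationError("both groups need at least 3 cells")
    a = mat.select_obs(group_a).values
    b = mat.select_obs(group_b).values
    mean_a, mean_b = a.mean(axis=1), b.mean(axis=1)
    log2fc = np.log2(mean_a + pseudocount) - np.log2(mean_b + pseudocount)
    with np.errstate(all="ignore"):
        _, p = mannwhitneyu(a, b, axis=1, alternative="two-sided")
    p = np.clip(np.nan_to_num(p, nan=1.0), np.finfo(float).tiny, 1.0)
    p_adj = multipletests(p, method="fdr_bh")[1]
    return pd.DataFrame({"gene_id": mat.gene_ids, "log2fc": log2fc,
                         "p": p, "p_adj": p_adj})


def intersect_candidates(de_a: pd.DataFrame, de_b: pd.DataFrame,
                         p_adj_threshold: float = 0.05,
                         log2fc_threshold: float = 1.0) -> list[str]:
    """Genes significant (p_adj < thr and |log2FC| > thr) in BOTH tables, sorted."""
    def survivors(de: pd.DataFrame) -> set[str]:
        m = (de["p_adj"] < p_adj_threshold) & (de["log2fc"].abs() > log2fc_threshold)
        return set(de.loc[m, "gene_id"])

    out = sorted(survivors(de_a) & survivors(de_b))
    if not out:
        logger.info("candidate intersection is empty")
    return out


# ---------------------------------------------------------------------------
# Cox utilities
# ---------------------------------------------------------------------------

def breslow_partial_loglik(lp: np.ndarray, time: np.ndarray, event: np.ndarray) -> float:
    """Cox partial log-likelihood with Breslow tie handling."""
    lp = np.asarray(lp, float)
    order = np.argsort(time, kind="mergesort")
    lp, time, event = lp[order], np.asarray(time)[order], np.asarray(event)[order]
    # risk-set log-sum-exp computed from the tail
    m = lp.max()
    rev_cumsum = np.cumsum(np.exp(lp - m)[::-1])[::-1]
    ll = 0.0
    i = 0
    n = len(lp)
    while i < n:
        j = i
        while j < n and time[j] == time[i]:
            j += 1
        d = [k for k in range(i, j) if event[k] == 1]
        if d:
            log_risk = m + np.log(rev_cumsum[i])
            ll += float(lp[d].sum()) - len(d) * log_risk
        i = j
    return ll


def _standardize(X: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series, pd.Series]:
    mean, sd = X.mean(), X.std(ddof=1)
    sd = sd.replace(0.0, 1.0)
    return (X - mean) / sd, mean, sd


def _gene_frame(cohort: SurvivalCohort, genes: list[str]) -> pd.DataFrame:
    missing = [g for g in genes if g not in set(cohort.expression.gene_ids)]
    if missing:
        raise ValidationError(f"genes absent from cohort expression: {missing[:10]}")
    df = cohort.expression.to_frame().loc[genes].T  # samples x genes
    return df


def univariate_cox_screen(cohort: SurvivalCohort, genes: list[str],
                          p_threshold: float = 0.05) -> pd.DataFrame:
    """Per-gene univariate Cox PH on standardized expression; keep p < threshold.

    Returns a table (gene_id, hr, coef, p) of the retained genes.  Genes
    whose fit fails to converge are dropped with a warning.
    """
    if cohort.event.sum() < 10:
        raise ValidationError("univariate screen needs at least 10 events")
    X, _, _ = _standardize(_gene_frame(cohort, genes))
    rows = []
    for g in genes:
        df = pd.DataFrame({"time": cohort.time, "event": cohort.event, "x": X[g].to_numpy()})
        try:
            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                cph = CoxPHFitter().fit(df, "time", "event")
        except Exception as exc:  # convergence failure on a degenerate gene
            warnings.warn(f"univariate Cox failed for {g}: {exc}")
            continue
        rows.append({"gene_id": g, "hr": float(np.exp(cph.params_["x"])),
                     "coef": float(cph.params_["x"]),
                     "p": float(cph.summary.loc["x", "p"])})
    table = pd.DataFrame(rows, columns=["gene_id", "hr", "coef", "p"])
    return table[table["p"] < p_threshold].reset_index(drop=True)


def lasso_cox_select(cohort: SurvivalCohort, genes: list[str], n_folds: int = 10,
                     seed: int = 0, n_alphas: int = 50) -> tuple[list[str], float, pd.DataFrame]:
    """L1-penalized Cox path with lambda at minimum CV partial-likelihood deviance.

    Folds are stratified by event status and seeded.  Returns
    ``(selected genes, lambda, cv table)``; raises when every coefficient is
    zero at the chosen lambda.
    """
    if len(genes) < 2:
        raise ValidationError("LASSO needs at least 2 candidate genes")
    X, _, _ = _standardize(_gene_frame(cohort, genes))
    y = Surv.from_arrays(cohort.event.astype(bool), cohort.time)
    path = CoxnetSurvivalAnalysis(l1_ratio=1.0, n_alphas=n_alphas, alpha_min_ratio=0.01)
    path.fit(X.to_numpy(), y)
    alphas = np.asarray(path.alphas_)

    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    dev = np.zeros((n_folds, len(alphas)))
    for f, (tr, te) in enumerate(skf.split(X, cohort.event)):
        if cohort.event[te].sum() == 0 or cohort.event[tr].sum() == 0:
            raise ValidationError("a CV fold has no events; reduce n_folds")
        fold = CoxnetSurvivalAnalysis(l1_ratio=1.0, alphas=alphas, fit_baseline_model=False)
        fold.fit(X.to_numpy()[tr], y[tr])
        for a, alpha in enumerate(alphas):
            # predict interpolates the path if the fold stopped early
            lp = fold.predict(X.to_numpy()[te], alpha=alpha)
            dev[f, a] = -2.0 * breslow_partial_loglik(lp, cohort.time[te], cohort.event[te])
    mean_dev = dev.mean(axis=0)
    best = int(np.argmin(mean_dev))
    lam = float(alphas[best])
    coef = path.coef_[:, best]
    selected = [g for g, c in zip(genes, coef) if c != 0.0]
    if not selected:
        raise ValidationError("all coefficients zero at lambda_min; review screening thresholds")
    cv = pd.DataFrame({"alpha": alphas, "mean_deviance": mean_dev})
    return selected, lam, cv


# ---------------------------------------------------------------------------
# risk model
# ---------------------------------------------------------------------------

@dataclass
class SurvivalEval:
    """Evaluation bundle for a fitted risk stratification."""

    logrank_stat: float
    logrank_p: float
    auc: dict[float, float]
    hr: float
    hr_ci: tuple[float, float]
    hr_p: float
    hr_adjusted: float | None = None
    hr_adjusted_ci: tuple[float, float] | None = None
    hr_adjusted_p: float | None = None
    flags: list[str] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["auc"] = {str(k): v for k, v in self.auc.items()}
        Path(path).write_text(json.dumps(d, indent=2))


class RiskScoreModel(BaseEstimator):
    """Median-stratified Cox risk score over a selected gene panel.

    ``fit`` runs univariate screen -> LASSO path -> multivariate Cox on a
    :class:`SurvivalCohort`; ``predict`` maps expression to risk scores with
    the training standardization.

    Parameters
    ----------
    screen_p : float
        Univariate Cox retention threshold.
    n_folds : int
        Cross-validation folds for the penalty path.
    seed : int
        Fold-assignment seed.

    Attributes
    ----------
    genes_ : selected gene panel (nonzero at lambda_min).
    coef_ : multivariate Cox coefficients (standardized-expression scale).
    lambda_ : chosen L1 penalty.
    scores_ : per-sample risk scores of the training cohort.
    cutoff_ : median training score; score > cutoff -> high risk.
    groups_ : "high"/"low" per training sample.
    """

    def __init__(self, screen_p: float = 0.05, n_folds: int = 10, seed: int = 0,
                 skip_screen: bool = False):
        self.screen_p = screen_p
        self.n_folds = n_folds
        self.seed = seed
        self.skip_screen = skip_screen

    def fit(self, cohort: SurvivalCohort, candidate_genes: list[str] | None = None
            ) -> "RiskScoreModel":
        genes = list(candidate_genes) if candidate_genes else list(cohort.expression.gene_ids)
        if not self.skip_screen:
            screen = univariate_cox_screen(cohort, genes, self.screen_p)
            self.screen_ = screen
            genes = screen["gene_id"].tolist()
            if not genes:
                raise ValidationError("no genes survive the univariate screen")
        selected, lam, cv = lasso_cox_select(cohort, genes, self.n_folds, self.seed)
        self.lambda_ = lam
        self.cv_path_ = cv

        X = _gene_frame(cohort, selected)
        Xz, self.train_mean_, self.train_sd_ = _standardize(X)
        df = Xz.copy()
        df["time"], df["event"] = cohort.time, cohort.event
        cph = CoxPHFitter(penalizer=1e-6).fit(df, "time", "event")
        coef = cph.params_.loc[selected]
        if np.allclose(coef, 0.0):
            raise ValidationError("degenerate multivariate fit: all coefficients zero")
        self.genes_ = selected
        self.coef_ = coef
        self.cox_summary_ = cph.summary
        self.scores_ = pd.Series(Xz.to_numpy() @ coef.to_numpy(),
                                 index=cohort.expression.obs_ids, name="risk_score")
        self.cutoff_ = float(self.scores_.median())
        self.groups_ = stratify_by_median(self.scores_, self.cutoff_)
        return self

    def predict(self, expression: ExpressionMatrix | pd.DataFrame) -> pd.Series:
        """Risk scores for new samples (training standardization applied)."""
        if not hasattr(self, "coef_"):
            raise ValidationError("RiskScoreModel is not fitted")
        df = expression.to_frame().T if isinstance(expression, ExpressionMatrix) else expression
        missing = [g for g in self.genes_ if g not in df.columns]
        if missing:
            raise ValidationError(f"expression lacks model genes: {missing}")
        Xz = (df[self.genes_] - self.train_mean_) / self.train_sd_
        return pd.Series(Xz.to_numpy() @ self.coef_.to_numpy(), index=df.index,
                         name="risk_score")

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps({
            "genes": self.genes_, "coefficients": self.coef_.to_dict(),
            "lambda": self.lambda_, "cutoff": self.cutoff_,
            "standardization": {"mean": self.train_mean_.to_dict(),
                                "sd": self.train_sd_.to_dict()},
            "tie_rule": "score > median -> high risk",
        }, indent=2))


def stratify_by_median(scores: pd.Series, cutoff: float | None = None) -> pd.Series:
    """'high' where score strictly exceeds the median, else 'low'."""
    if cutoff is None:
        cutoff = float(scores.median())
    return pd.Series(np.where(scores > cutoff, "high", "low"),
                     index=scores.index, name="risk_group")


def fit_risk_model(cohort: SurvivalCohort, selected_genes: list[str]) -> RiskScoreModel:
    """Multivariate Cox + median stratification on an already-selected panel."""
    if not selected_genes:
        raise ValidationError("selected gene list is empty")
    model = RiskScoreModel(skip_screen=True)
    # bypass the LASSO stage: fit multivariate Cox directly
    X = _gene_frame(cohort, selected_genes)
    Xz, model.train_mean_, model.train_sd_ = _standardize(X)
    df = Xz.copy()
    df["time"], df["event"] = cohort.time, cohort.event
    cph = CoxPHFitter(penalizer=1e-6).fit(df, "time", "event")
    coef = cph.params_.loc[selected_genes]
    if np.allclose(coef, 0.0):
        raise ValidationError("degenerate multivariate fit: all coefficients zero")
    model.genes_ = list(selected_genes)
    model.coef_ = coef
    model.lambda_ = float("nan")
    model.cox_summary_ = cph.summary
    model.scores_ = pd.Series(Xz.to_numpy() @ coef.to_numpy(),
                              index=cohort.expression.obs_ids, name="risk_score")
    model.cutoff_ = float(model.scores_.median())
    model.groups_ = stratify_by_median(model.scores_, model.cutoff_)
    return model


# ---------------------------------------------------------------------------
# evaluation
# ---------------------------------------------------------------------------

def censoring_survival(time: np.ndarray, event: np.ndarray) -> KaplanMeierFitter:
    """Kaplan-Meier estimate of the censoring distribution G(t)."""
    km = KaplanMeierFitter()
    km.fit(time, 1 - np.asarray(event))
    return km


def ipcw_time_auc(time: np.ndarray, event: np.ndarray, score: np.ndarray,
                  horizons=DEFAULT_HORIZONS) -> dict[float, float]:
    """Cumulative/dynamic time-dependent AUC with IPCW.

    Cases at horizon t are subjects with an observed event at or before t,
    weighted by 1/G(T-); controls are subjects still at risk after t.
    Score ties count 1/2, so a constant score gives exactly 0.5.
    """
    time = np.asarray(time, float)
    event = np.asarray(event, int)
    score = np.asarray(score, float)
    if np.ptp(time) > 0 and max(horizons) > time.max():
        warnings.warn("a horizon exceeds the observed follow-up")
    km = censoring_survival(time, event)

    def G_minus(t: np.ndarray) -> np.ndarray:
        return np.clip(km.survival_function_at_times(t - 1e-9).to_numpy(), 1e-12, None)

    out: dict[float, float] = {}
    for t in horizons:
        cases = (time <= t) & (event == 1)
        controls = time > t
        if cases.sum() == 0 or controls.sum() == 0:
            out[float(t)] = float("nan")
            continue
        w = np.zeros_like(time)
        w[cases] = 1.0 / G_minus(time[cases])
        sc, scr = score[cases], score[controls]
        wc = w[cases]
        n_ctrl = int(controls.sum())
        greater = (sc[:, None] > scr[None, :]).sum(axis=1)
        ties = (sc[:, None] == scr[None, :]).sum(axis=1)
        # per-case placement probability; exact 0.5 under all-tied scores
        p_case = (greater + 0.5 * ties) / n_ctrl
        out[float(t)] = float((wc * p_case).sum() / wc.sum())
    return out


def evaluate_model(scores: pd.Series, cohort: SurvivalCohort,
                   horizons=DEFAULT_HORIZONS,
                   covariates: list[str] | None = None) -> SurvivalEval:
    """Evaluate a risk score against a cohort.

    Median-split KM/log-rank, IPCW time-dependent AUC at each horizon, and
    Cox HR of the continuous score alone and adjusted for the requested
    covariate columns of the survival table.
    """
    scores = scores.loc[cohort.expression.obs_ids]
    groups = stratify_by_median(scores)
    time, event = cohort.time, cohort.event
    hi = groups.to_numpy() == "high"
    flags = []
    for name, mask in [("high", hi), ("low", ~hi)]:
        if event[mask].sum() == 0:
            flags.append(f"{name}-risk group has zero events")
    lr = logrank_test(time[hi], time[~hi], event[hi], event[~hi])

    auc = ipcw_time_auc(time, event, scores.to_numpy(), horizons)

    def cox_hr(cols: pd.DataFrame) -> tuple[float, tuple[float, float], float]:
        df = cols.copy()
        df["time"], df["event"] = time, event
        cph = CoxPHFitter(penalizer=1e-6).fit(df, "time", "event")
        s = cph.summary.loc["score"]
        return (float(s["exp(coef)"]),
                (float(s["exp(coef) lower 95%"]), float(s["exp(coef) upper 95%"])),
                float(s["p"]))

    hr, ci, p = cox_hr(pd.DataFrame({"score": scores.to_numpy()}))
    ev = SurvivalEval(float(lr.test_statistic), float(lr.p_value), auc, hr, ci, p,
                      flags=flags)
    if covariates:
        missing = [c for c in covariates if c not in cohort.table.columns]
        if missing:
            raise ValidationError(f"covariates absent from survival table: {missing}")
        cols = cohort.table[covariates].reset_index(drop=True).copy()
        cols.insert(0, "score", scores.to_numpy())
        ev.hr_adjusted, ev.hr_adjusted_ci, ev.hr_adjusted_p = cox_hr(cols)
    return ev


def score_signature_survival(bulk: ExpressionMatrix, cohort: SurvivalCohort,
                             signature: list[str]) -> dict:
    """Mean-signature-expression median split with KM/log-rank.

    Returns the per-sample signature score, group labels, the log-rank
    statistic/p and per-group KM curves.
    """
    matched = [g for g in signature if g in set(bulk.gene_ids)]
    if not matched:
        raise ValidationError("signature shares no genes with the bulk matrix")
    if bulk.n_obs < 2:
        raise ValidationError("need at least 2 samples for a median split")
    score = bulk.to_frame().loc[matched].mean(axis=0)
    score = score.loc[cohort.expression.obs_ids]
    groups = stratify_by_median(score)
    hi = groups.to_numpy() == "high"
    time, event = cohort.time, cohort.event
    lr = logrank_test(time[hi], time[~hi], event[hi], event[~hi])
    km = {}
    for name, mask in [("high", hi), ("low", ~hi)]:
        fitter = KaplanMeierFitter().fit(time[mask], event[mask], label=name)
        km[name] = fitter.survival_function_
    return {"score": score, "groups": groups, "logrank_stat": float(lr.test_statistic),
            "logrank_p": float(lr.p_value), "km": km, "n_matched_genes": len(matched)}
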