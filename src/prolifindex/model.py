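"""Dichotomized cross-cancer survival classifiers and their permutation null.

Per cancer, the k shortest-surviving uncensored patients (outcome 0) and the k
longest-surviving patients (outcome 1, censored eligible) form an
extreme-survivor cohort; gene expression is z-scaled within each cancer before
cohorts are combined, and a 70/30 outcome-stratified split separates training
from testing.  The core families are L1- and L2-penalized binomial regression
with the penalty chosen by 5-fold cross validation and the one-standard-error
rule; random forest and linear SVM are robustness alternatives behind the same
interface.  Performance is test-set ROC-AUC; two correlated AUCs are compared
with DeLong's paired test.  The permutation null refits the whole pipeline on
random cancer subsets to ask whether the PIC-only model's AUC is exceptional.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from math import ceil

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve
from sklearn.svm import SVC

from .io import ExpressionMatrix, ValidationError
from .survival import km_quartile_test, KMQuartileResult

logger = logging.getLogger(__name__)

MODEL_FAMILIES = ("lasso", "ridge", "random_forest", "linear_svm")


@dataclass
class DichotomizedDesign:
    """Extreme-survivor cohorts with (after scaling) features and a split."""

    assignments: pd.DataFrame      # sample_id, cancer_type, outcome, survival_days, event
    k: int
    excluded_cancers: list[str] = field(default_factory=list)
    features: pd.DataFrame | None = None   # samples x genes, per-cancer scaled
    train_ids: list[str] = field(default_factory=list)
    test_ids: list[str] = field(default_factory=list)

    @property
    def outcomes(self) -> pd.Series:
        return self.assignments.set_index("sample_id")["outcome"]


@dataclass
class FittedModel:
    family: str
    coefficients: pd.Series | None         # linear families only
    intercept: float | None
    hyperparameters: dict
    cv_trace: pd.DataFrame | None
    estimator: object
    feature_names: list[str]
    seed: int

    def score(self, X: pd.DataFrame) -> np.ndarray:
        """Continuous risk score (higher = predicted long survival, outcome 1)."""
        Xm = X[self.feature_names].to_numpy()
        if self.family in ("lasso", "ridge"):
            return Xm @ self.coefficients.to_numpy() + self.intercept
        if self.family == "linear_svm":
            return self.estimator.decision_function(Xm)
        return self.estimator.predict_proba(Xm)[:, 1]


@dataclass
class ModelEval:
    fpr: np.ndarray
    tpr: np.ndarray
    thresholds: np.ndarray
    auc: float
    test_ids: list[str]


@dataclass
class PermutationRun:
    draws: pd.DataFrame            # cancers, n_pics, auc per draw
    rho: float                     # Spearman rho(#PICs, AUC); NaN if degenerate
    rho_p: float
    reference_auc: float | None
    empirical_p: float | None      # exceedance p of the reference AUC
    n_redraws: int


def dichotomize(cohort: pd.DataFrame, k: int = 18) -> DichotomizedDesign:
    """Select per cancer the k shortest-surviving uncensored patients (outcome 0)
    and the k longest-surviving patients (outcome 1; censored eligible).

    Ties at the k-th position keep the lexicographically smaller sample id.
    Cancers with fewer than k uncensored deaths or 2k patients are excluded
    with a warning.
    """
    rows, excluded = [], []
    for cancer, sub in cohort.groupby("cancer_type", sort=False):
        deaths = sub[sub["event"]]
        if len(deaths) < k or len(sub) < 2 * k:
            excluded.append(cancer)
            continue
        short = deaths.sort_values(["survival_days", "sample_id"]).head(k)
        rest = sub[~sub["sample_id"].isin(short["sample_id"])]
        long_ = rest.sort_values(["survival_days", "sample_id"],
                                 ascending=[False, True]).head(k)
        for df, outcome in ((short, 0), (long_, 1)):
            part = df[["sample_id", "cancer_type", "survival_days", "event"]].copy()
            part["outcome"] = outcome
            rows.append(part)
    if excluded:
        warnings.warn(f"cancers excluded from dichotomization (need >= {k} deaths "
                      f"and >= {2 * k} patients): {excluded}", stacklevel=2)
    if not rows:
        raise ValidationError("no cancer satisfies the dichotomization preconditions")
    assignments = pd.concat(rows, ignore_index=True)
    return DichotomizedDesign(assignments=assignments, k=k, excluded_cancers=excluded)


def scale_and_partition(expr_by_cancer: dict[str, ExpressionMatrix],
                        design: DichotomizedDesign, seed: int,
                        train_frac: float = 0.7) -> DichotomizedDesign:
    """Z-scale genes within each cancer over the design samples, combine, and
    split 70/30 stratified by outcome (ceil convention on the training side)."""
    blocks = []
    for cancer, sub in design.assignments.groupby("cancer_type", sort=False):
        expr = expr_by_cancer[cancer]
        if expr.normalization != "vst":
            raise ValidationError(f"expression for {cancer!r} must be VST-normalized")
        X = expr.data.loc[:, sub["sample_id"]].to_numpy(dtype=float)
        mean = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        flat = sd[:, 0] == 0
        if flat.any():
            logger.warning("%s: %d zero-variance genes scaled to 0", cancer, flat.sum())
        Xs = np.where(sd > 0, (X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
        blocks.append(pd.DataFrame(Xs.T, index=sub["sample_id"], columns=expr.gene_ids))
    features = pd.concat(blocks)

    rng = np.random.default_rng(seed)
    outcomes = design.outcomes
    train_ids: list[str] = []
    test_ids: list[str] = []
    for outcome in (0, 1):
        ids = np.asarray(sorted(outcomes.index[outcomes == outcome]))
        rng.shuffle(ids)
        n_train = ceil(train_frac * len(ids))
        train_ids.extend(ids[:n_train])
        test_ids.extend(ids[n_train:])
    return DichotomizedDesign(assignments=design.assignments, k=design.k,
                              excluded_cancers=design.excluded_cancers,
                              features=features, train_ids=sorted(train_ids),
                              test_ids=sorted(test_ids))


def _binomial_deviance(y, p):
    eps = 1e-12
    p = np.clip(p, eps, 1 - eps)
    return -2.0 * np.mean(y * np.log(p) + (1 - y) * np.log(1 - p))


def _cv_folds(y, n_folds, rng):
    """Outcome-stratified fold assignment."""
    folds = np.empty(len(y), dtype=int)
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        folds[idx] = np.arange(len(idx)) % n_folds
    return folds

def _fit_glmnet_like(X, y, alpha_l1: bool, seed: int, n_folds: int = 5,
                     n_lambda: int = 30, cv_loss: str = "deviance"):
    """Penalized binomial regression with a lambda path, 5-fold CV, and the
    1-SE rule (the sparsest/strongest penalty within one standard error of the
    minimum cross-validation loss)."""
    n, p = X.shape
    ybar = y.mean()
    lam_max = np.max(np.abs(X.T @ (y - ybar))) / n
    if not alpha_l1:
        lam_max *= 100.0           # ridge needs a far larger penalty to saturate
    lam_grid = np.geomspace(lam_max, lam_max * 1e-3, n_lambda)

    rng = np.random.default_rng(seed)
    folds = _cv_folds(y, n_folds, rng)

    def make_est(lam):
        C = 1.0 / (n * lam)
        if alpha_l1:
            return LogisticRegression(l1_ratio=1.0, C=C, solver="liblinear",
                                      max_iter=1000)
        return LogisticRegression(l1_ratio=0.0, C=C, solver="lbfgs", max_iter=1000)

    losses = np.empty((n_lambda, n_folds))
    for i, lam in enumerate(lam_grid):
        for f in range(n_folds):
            tr, te = folds != f, folds == f
            est = make_est(lam).fit(X[tr], y[tr])
            prob = est.predict_proba(X[te])[:, 1]
            if cv_loss == "deviance":
                losses[i, f] = _binomial_deviance(y[te], prob)
            else:
                losses[i, f] = np.mean((y[te] - prob) ** 2)
    mean_loss = losses.mean(axis=1)
    se_loss = losses.std(axis=1, ddof=1) / np.sqrt(n_folds)
    i_min = int(np.argmin(mean_loss))
    threshold = mean_loss[i_min] + se_loss[i_min]
    i_1se = int(np.flatnonzero(mean_loss <= threshold)[0])   # largest lambda within 1 SE
    lam = lam_grid[i_1se]
    est = make_est(lam).fit(X, y)
    trace = pd.DataFrame({"lambda": lam_grid, "cv_loss": mean_loss, "cv_se": se_loss})
    return est, lam, trace


def fit_model(design: DichotomizedDesign, family: str = "lasso",
              seed: int = 0, cv_loss: str = "deviance") -> FittedModel:
    """Fit one model family on the training partition of a scaled design."""
    if family not in MODEL_FAMILIES:
        raise ValueError(f"unknown family {family!r}")
    if design.features is None or not design.train_ids:
        raise ValidationError("design has no features/partition; run scale_and_partition")
    X = design.features.loc[design.train_ids]
    y = design.outcomes.loc[design.train_ids].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValidationError("single-class training set")
    Xm = X.to_numpy()

    if family in ("lasso", "ridge"):
        est, lam, trace = _fit_glmnet_like(Xm, y, alpha_l1=(family == "lasso"),
                                           seed=seed, cv_loss=cv_loss)
        coef = pd.Series(est.coef_[0], index=X.columns)
        return FittedModel(family, coef, float(est.intercept_[0]),
                           {"lambda": float(lam), "alpha": 1.0 if family == "lasso" else 0.0,
                            "nfolds": 5, "rule": "1se", "cv_loss": cv_loss},
                           trace, est, X.columns.tolist(), seed)
    if family == "random_forest":
        est = RandomForestClassifier(n_estimators=500,
                                     max_features=min(1000, Xm.shape[1]),
                                     random_state=seed).fit(Xm, y)
        return FittedModel(family, None, None,
                           {"mtry": min(1000, Xm.shape[1]), "n_estimators": 500},
                           None, est, X.columns.tolist(), seed)
    # linear SVM: cost grid 1e-5 .. 1e4 in decade steps, 5-fold CV error
    rng = np.random.default_rng(seed)
    folds = _cv_folds(y, 5, rng)
    costs = 10.0 ** np.arange(-5, 5)
    errs = []
    for c in costs:
        fold_err = []
        for f in range(5):
            tr, te = folds != f, folds == f
            est = SVC(kernel="linear", C=c).fit(Xm[tr], y[tr])
            pred = est.predict(Xm[te])
            fold_err.append(np.mean((y[te] - pred) ** 2))
        errs.append(np.mean(fold_err))
    best = costs[int(np.argmin(errs))]
    est = SVC(kernel="linear", C=best).fit(Xm, y)
    trace = pd.DataFrame({"cost": costs, "cv_error": errs})
    return FittedModel("linear_svm", None, None, {"cost": float(best), "nfolds": 5},
                       trace, est, X.columns.tolist(), seed)


def evaluate_model(model: FittedModel, design: DichotomizedDesign) -> ModelEval:
    """Test-partition ROC and trapezoid AUC."""
    if not design.test_ids:
        raise ValidationError("design has no test partition")
    X = design.features.loc[design.test_ids]
    y = design.outcomes.loc[design.test_ids].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValidationError("single-class test set: AUC undefined")
    scores = model.score(X)
    fpr, tpr, thr = roc_curve(y, scores)
    auc = float(np.trapezoid(tpr, fpr))
    return ModelEval(fpr, tpr, thr, auc, list(design.test_ids))


# ---------------------------------------------------------------------------
# DeLong's test for two correlated AUCs


def _midrank(x):
    order = np.argsort(x, kind="mergesort")
    ranks = np.empty(len(x))
    sorted_x = x[order]
    i = 0
    k = 1
    while i < len(x):
        j = i
        while j < len(x) and sorted_x[j] == sorted_x[i]:
            j += 1
        ranks[order[i:j]] = 0.5 * (i + j - 1) + 1
        i = j
        k += 1
    return ranks


def delong_test(scores_a, scores_b, labels) -> tuple[float, float]:
    """DeLong's paired test of two correlated ROC AUCs on the same test set.

    Returns ``(z, two_sided_p)``.
    """
    labels = np.asarray(labels).astype(int)
    pos, neg = labels == 1, labels == 0
    m, n = pos.sum(), neg.sum()
    if m == 0 or n == 0:
        raise ValidationError("DeLong test needs both classes")
    aucs, v10, v01 = [], [], []
    for s in (np.asarray(scores_a, float), np.asarray(scores_b, float)):
        tx = _midrank(s[pos])
        ty = _midrank(s[neg])
        tz = _midrank(s)
        auc = (tz[pos].sum() - m * (m + 1) / 2) / (m * n)
        aucs.append(auc)
        v10.append((tz[pos] - tx) / n)
        v01.append(1.0 - (tz[neg] - ty) / m)
    aucs = np.asarray(aucs)
    v10 = np.vstack(v10)
    v01 = np.vstack(v01)
    s10 = np.cov(v10)
    s01 = np.cov(v01)
    cov = s10 / m + s01 / n
    var = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var <= 0:
        return 0.0, 1.0
    z = (aucs[0] - aucs[1]) / np.sqrt(var)
    return float(z), float(2 * stats.norm.sf(abs(z)))


def permutation_null(cohort: pd.DataFrame,
                     expr_by_cancer: dict[str, ExpressionMatrix],
                     pic_cancers: list[str],
                     n_draws: int = 1000, set_size: int = 7,
                     family: str = "lasso", seed: int = 0, k: int = 18,
                     reference_auc: float | None = None) -> PermutationRun:
    """Random-cancer-set null for the PIC-only model.

    Each draw samples ``set_size`` distinct cancers, dichotomizes, scales,
    splits, fits ``family``, and records the test AUC together with the number
    of PICs in the draw.  Failed draws (single-class partitions) are redrawn.
    """
    eligible = [c for c in cohort["cancer_type"].unique()
                if (cohort["cancer_type"] == c).sum() >= 2 * k
                and cohort.loc[cohort["cancer_type"] == c, "event"].sum() >= k]
    if len(eligible) < set_size:
        raise ValidationError("not enough eligible cancers for the requested set size")
    rng = np.random.default_rng(seed)
    pic_set = set(pic_cancers)
    records = []
    n_redraws = 0
    while len(records) < n_draws:
        draw = sorted(rng.choice(eligible, size=set_size, replace=False))
        sub = cohort[cohort["cancer_type"].isin(draw)]
        try:
            design = dichotomize(sub, k=k)
            design = scale_and_partition(expr_by_cancer, design,
                                         seed=int(rng.integers(2**31)))
            model = fit_model(design, family=family, seed=int(rng.integers(2**31)))
            ev = evaluate_model(model, design)
        except ValidationError as exc:
            n_redraws += 1
            logger.warning("permutation draw failed (%s); redrawn", exc)
            continue
        records.append({"cancers": ",".join(draw),
                        "n_pics": len(pic_set.intersection(draw)),
                        "auc": ev.auc})
    draws = pd.DataFrame(records)
    if draws["n_pics"].nunique() > 1:
        res = stats.spearmanr(draws["n_pics"], draws["auc"])
        rho, rho_p = float(res.statistic), float(res.pvalue)
    else:
        warnings.warn("number of PICs constant across draws; rho undefined", stacklevel=2)
        rho, rho_p = float("nan"), float("nan")
    emp_p = None
    if reference_auc is not None:
        emp_p = float((1 + (draws["auc"] >= reference_auc).sum()) / (n_draws + 1))
    return PermutationRun(draws, rho, rho_p, reference_auc, emp_p, n_redraws)


@dataclass
class FullCohortResult:
    table: pd.DataFrame            # per cancer: flag, n_eval, logrank stat, p
    km: dict[str, KMQuartileResult]


def full_cohort_assessment(model: FittedModel, cohort: pd.DataFrame,
                           expr_by_cancer: dict[str, ExpressionMatrix],
                           design: DichotomizedDesign,
                           cancers: list[str] | None = None,
                           min_heldout: int = 25) -> FullCohortResult:
    """Score every patient of each (PIC) cancer with a fitted model and compare
    top vs bottom predicted quartiles by Kaplan-Meier/log-rank.

    Cancers with more than ``min_heldout`` uncensored patients outside the
    training set are evaluated on non-training patients only (``held_out``);
    the rest are evaluated on the full cohort (``includes_training``).
    """
    train = set(design.train_ids)
    rows = {}
    kms = {}
    cancers = cancers or sorted(cohort["cancer_type"].unique())
    for cancer in cancers:
        sub = cohort[cohort["cancer_type"] == cancer]
        expr = expr_by_cancer[cancer]
        missing = [g for g in model.feature_names if g not in expr.data.index]
        if missing:
            raise ValidationError(f"{cancer}: genes missing for scoring: {missing[:5]}")
        X = expr.data.loc[model.feature_names, sub["sample_id"]].to_numpy(dtype=float)
        mean = X.mean(axis=1, keepdims=True)
        sd = X.std(axis=1, keepdims=True)
        Xs = np.where(sd > 0, (X - mean) / np.where(sd > 0, sd, 1.0), 0.0)
        feats = pd.DataFrame(Xs.T, index=sub["sample_id"], columns=model.feature_names)

        non_train = sub[~sub["sample_id"].isin(train)]
        n_heldout_deaths = int(non_train["event"].sum())
        if n_heldout_deaths > min_heldout:
            eval_sub, flag = non_train, "held_out"
        else:
            eval_sub, flag = sub, "includes_training"
        scores = model.score(feats.loc[eval_sub["sample_id"]])
        res = km_quartile_test(eval_sub["survival_days"], eval_sub["event"], scores)
        rows[cancer] = {"flag": flag, "n_eval": len(eval_sub),
                        "logrank_statistic": res.statistic, "p_value": res.p_value}
        kms[cancer] = res
    return FullCohortResult(pd.DataFrame.from_dict(rows, orient="index"), kms)
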