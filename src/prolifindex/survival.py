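"""Cox survival association, cross-cancer signature selection, and PIC calls.

The single-covariate Cox proportional-hazards fit maximizes the Efron
tie-corrected partial likelihood by Newton's method and reports Wald p-values.
Fits that fail to converge — almost always a coefficient running to infinity
under monotone separation — are assigned p = 1, the convention the downstream
p-value matrix relies on for completeness.  The per-transcript scan runs the
same Newton iteration batched across genes (one covariate per row), which is
what makes a transcriptome-wide scan per cancer affordable.

A proliferation-informative cancer (PIC) is a cancer whose PI survival
association survives Bonferroni correction across cancers at 0.05.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats
from scipy.cluster import hierarchy

from .io import ExpressionMatrix, GeneSet, ValidationError
from .index import PIVector

logger = logging.getLogger(__name__)

COEF_BOUND = 15.0     # |coefficient| beyond which the MLE is treated as infinite
NEWTON_TOL = 1e-9
NEWTON_MAX_ITER = 50


@dataclass
class CoxFit:
    coefficient: float
    standard_error: float
    wald_z: float
    p_value: float
    n: int
    n_events: int
    converged: bool


@dataclass
class PICLabelSet:
    """Per-cancer PI Cox p-values with Bonferroni correction and PIC flags."""

    table: pd.DataFrame            # index cancer; p_value, [p_corrected, is_pic]

    @property
    def pics(self) -> list[str]:
        if "is_pic" not in self.table.columns:
            raise ValidationError("PIC labels not assigned yet; run identify_pics")
        return self.table.index[self.table["is_pic"]].tolist()


@dataclass
class ClusterResult:
    linkage: np.ndarray
    assignments: pd.Series         # cancer -> cluster id (1-based)
    heights: np.ndarray


def _cox_newton_batch(time, event, X):
    """Newton-Raphson on the Efron partial likelihood, batched over covariates.

    ``X`` is covariates x observations.  Returns arrays
    ``(beta, se, p, converged)`` of length ``X.shape[0]``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    X = np.atleast_2d(np.asarray(X, dtype=float))
    n_cov, n = X.shape

    beta = np.zeros(n_cov)
    se = np.full(n_cov, np.nan)
    p = np.ones(n_cov)
    converged = np.zeros(n_cov, dtype=bool)

    usable = X.std(axis=1) > 0
    if event.sum() < 2 or not usable.any():
        return beta, se, p, converged

    order = np.argsort(time, kind="stable")
    t = time[order]
    d = event[order]
    Xs = X[np.ix_(np.flatnonzero(usable), order)]

    event_idx = np.flatnonzero(d)
    et = t[event_idx]
    new_group = np.empty(len(event_idx), dtype=bool)
    new_group[0] = True
    new_group[1:] = et[1:] != et[:-1]
    grp_bound = np.flatnonzero(new_group)                 # starts within event_idx
    group_sizes = np.diff(np.append(grp_bound, len(event_idx)))
    risk_start = np.searchsorted(t, et[new_group], side="left")
    # per-event replication of its group index and Efron fraction l/d
    group_rep = np.repeat(np.arange(len(grp_bound)), group_sizes)
    frac = np.concatenate([np.arange(k) / k for k in group_sizes])

    Xe = Xs[:, event_idx]
    sum_x_events = Xe.sum(axis=1)

    def moments(b):
        logw = np.clip(b[:, None] * Xs, -700.0, 700.0)
        W = np.exp(logw)
        XW = Xs * W
        X2W = Xs * XW
        S0 = np.cumsum(W[:, ::-1], axis=1)[:, ::-1]
        S1 = np.cumsum(XW[:, ::-1], axis=1)[:, ::-1]
        S2 = np.cumsum(X2W[:, ::-1], axis=1)[:, ::-1]
        We = W[:, event_idx]
        D0 = np.add.reduceat(We, grp_bound, axis=1)
        D1 = np.add.reduceat(Xe * We, grp_bound, axis=1)
        D2 = np.add.reduceat(Xe * Xe * We, grp_bound, axis=1)
        Z0 = S0[:, risk_start][:, group_rep] - frac * D0[:, group_rep]
        Z1 = S1[:, risk_start][:, group_rep] - frac * D1[:, group_rep]
        Z2 = S2[:, risk_start][:, group_rep] - frac * D2[:, group_rep]
        mean = Z1 / Z0
        grad = sum_x_events - mean.sum(axis=1)
        info = (Z2 / Z0 - mean * mean).sum(axis=1)
        return grad, info

    b = np.zeros(Xs.shape[0])
    done = np.zeros(Xs.shape[0], dtype=bool)
    diverged = np.zeros(Xs.shape[0], dtype=bool)
    info = np.full(Xs.shape[0], np.nan)
    for _ in range(NEWTON_MAX_ITER):
        grad, info = moments(b)
        bad = ~np.isfinite(info) | (info <= 0)
        diverged |= bad & ~done
        step = np.where(bad | done | diverged, 0.0, grad / np.where(info > 0, info, 1.0))
        b = b + step
        over = np.abs(b) > COEF_BOUND
        diverged |= over & ~done
        b = np.clip(b, -COEF_BOUND, COEF_BOUND)
        done |= (np.abs(step) < NEWTON_TOL) & ~diverged
        if (done | diverged).all():
            break

    ok = done & ~diverged & (info > 0)
    if ok.any():
        _, info_final = moments(b)
        ok &= np.isfinite(info_final) & (info_final > 0)
        se_ok = 1.0 / np.sqrt(info_final[ok])
        z = b[ok] / se_ok
        idx = np.flatnonzero(usable)[ok]
        beta[idx] = b[ok]
        se[idx] = se_ok
        p[idx] = 2.0 * stats.norm.sf(np.abs(z))
        converged[idx] = True
    # non-converged fits keep beta reported for diagnostics, p stays 1
    nc = ~ok
    if nc.any():
        beta[np.flatnonzero(usable)[nc]] = b[nc]
    return beta, se, p, converged


def cox_fit(time, event, covariate) -> CoxFit:
    """Single-covariate Cox PH fit (Efron ties, Newton, Wald p).

    A constant covariate, fewer than 2 events, or a coefficient running past
    ``COEF_BOUND`` yields ``converged=False`` with ``p_value=1``.
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    covariate = np.asarray(covariate, dtype=float)
    n, n_events = len(time), int(event.sum())
    if n_events < 2:
        logger.info("cox_fit: fewer than 2 events; returning p=1")
        return CoxFit(0.0, float("nan"), float("nan"), 1.0, n, n_events, False)
    if np.std(covariate) == 0:
        logger.info("cox_fit: constant covariate; returning p=1")
        return CoxFit(0.0, float("nan"), float("nan"), 1.0, n, n_events, False)
    beta, se, p, conv = _cox_newton_batch(time, event, covariate[None, :])
    wald = beta[0] / se[0] if conv[0] else float("nan")
    if not conv[0]:
        logger.info("cox_fit: non-convergence (coefficient nearing infinity); p set to 1")
    return CoxFit(float(beta[0]), float(se[0]), float(wald), float(p[0]),
                  n, n_events, bool(conv[0]))


def pi_survival_scan(cohort: pd.DataFrame, pi_by_cancer: dict[str, PIVector]) -> PICLabelSet:
    """One Cox fit of overall survival on PI per cancer (PI from VST data)."""
    rows = {}
    for cancer, sub in cohort.groupby("cancer_type", sort=False):
        if cancer not in pi_by_cancer:
            warnings.warn(f"no PI for cancer {cancer!r}; skipped", stacklevel=2)
            continue
        pi = pi_by_cancer[cancer].values.reindex(sub["sample_id"])
        fit = cox_fit(sub["survival_days"], sub["event"], pi)
        rows[cancer] = {"p_value": fit.p_value, "coefficient": fit.coefficient,
                        "n": fit.n, "n_events": fit.n_events, "converged": fit.converged}
    return PICLabelSet(pd.DataFrame.from_dict(rows, orient="index"))


def transcriptome_survival_scan(cohort: pd.DataFrame,
                                expr_by_cancer: dict[str, ExpressionMatrix],
                                min_variance: float = 0.0) -> pd.DataFrame:
    """Per-(cancer, transcript) Cox p-values; failed fits recorded as 1.

    Returns a complete cancers x transcripts p-value matrix.  Transcripts with
    within-cancer variance at or below ``min_variance`` are assigned p = 1 for
    that cancer (they cannot be fit anyway).
    """
    mats = {}
    for cancer, sub in cohort.groupby("cancer_type", sort=False):
        expr = expr_by_cancer[cancer]
        if expr.normalization != "vst":
            raise ValidationError(f"expression for {cancer!r} must be VST-normalized")
        X = expr.data.loc[:, sub["sample_id"]].to_numpy()
        keep = X.var(axis=1) > min_variance
        p = np.ones(X.shape[0])
        if keep.any():
            _, _, p_sub, _ = _cox_newton_batch(sub["survival_days"].to_numpy(),
                                               sub["event"].to_numpy(), X[keep])
            p[keep] = p_sub
        mats[cancer] = pd.Series(p, index=expr.gene_ids)
    pmat = pd.DataFrame(mats).T
    pmat.index.name = "cancer"
    return pmat


def select_shared_transcripts(pmat: pd.DataFrame, alpha: float = 0.05,
                              min_cancers: int = 9,
                              name: str = "shared_survival") -> GeneSet:
    """Transcripts with uncorrected Cox p < ``alpha`` in at least ``min_cancers``
    cancers (the cross-cancer shared survival signature)."""
    hits = (pmat < alpha).sum(axis=0)
    selected = hits.index[hits >= min_cancers].tolist()
    if not selected:
        warnings.warn("no transcript passes the shared-survival criterion", stacklevel=2)
    return GeneSet(name, selected, allow_empty=True)


def cluster_cancers(pmat: pd.DataFrame, transcripts: GeneSet,
                    n_clusters: int = 2) -> ClusterResult:
    """Ward (Ward.D2) hierarchical clustering of cancers on -log10 p profiles
    restricted to the selected transcripts, with an ``n_clusters`` cut."""
    if pmat.shape[0] < 2:
        raise ValidationError("need at least 2 cancers to cluster")
    genes = [g for g in transcripts if g in pmat.columns]
    if not genes:
        raise ValidationError("no selected transcript present in the p-value matrix")
    X = -np.log10(pmat[genes].to_numpy())
    Z = hierarchy.linkage(X, method="ward", metric="euclidean")
    labels = hierarchy.fcluster(Z, t=n_clusters, criterion="maxclust")
    return ClusterResult(Z, pd.Series(labels, index=pmat.index, name="cluster"),
                         Z[:, 2])


def identify_pics(scan: PICLabelSet, n_cancers: int | None = None,
                  alpha: float = 0.05) -> PICLabelSet:
    """Bonferroni-correct the PI scan (factor = number of cancers) and flag
    PICs: corrected p strictly below ``alpha``."""
    table = scan.table.copy()
    m = n_cancers if n_cancers is not None else len(table)
    table["p_corrected"] = np.minimum(1.0, table["p_value"] * m)
    table["is_pic"] = table["p_corrected"] < alpha
    return PICLabelSet(table)


@dataclass
class KMQuartileResult:
    statistic: float               # log-rank chi-square
    p_value: float
    n_low: int
    n_high: int
    km_low: pd.DataFrame           # survival function of the bottom-quartile group
    km_high: pd.DataFrame


def km_quartile_test(time, event, score, tie_policy: str = "extreme") -> KMQuartileResult:
    """Two-group log-rank test between the top and bottom quartiles of a score.

    Samples exactly at a quartile boundary are assigned to the extreme group
    (``tie_policy="extreme"``) or excluded (``"exclude"``).
    """
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=bool)
    score = np.asarray(score, dtype=float)
    if len(score) < 4:
        raise ValidationError("need at least 4 samples for quartile stratification")
    if np.std(score) == 0:
        raise ValidationError("constant score cannot be quartile-stratified")
    q1, q3 = np.percentile(score, [25, 75])
    if tie_policy == "extreme":
        low, high = score <= q1, score >= q3
    elif tie_policy == "exclude":
        low, high = score < q1, score > q3
    else:
        raise ValueError(f"unknown tie_policy {tie_policy!r}")
    if low.sum() == 0 or high.sum() == 0 or (low & high).any():
        raise ValidationError("degenerate quartile split (heavily tied scores)")
    res = logrank_test(time[low], time[high], event_observed_A=event[low],
                       event_observed_B=event[high])
    kms = []
    for mask in (low, high):
        km = KaplanMeierFitter().fit(time[mask], event[mask])
        kms.append(km.survival_function_)
    return KMQuartileResult(float(res.test_statistic), float(res.p_value),
                            int(low.sum()), int(high.sum()), kms[0], kms[1])


def linkage_to_newick(result: ClusterResult) -> str:
    """Render the cancer dendrogram as a Newick string (heights as branch lengths)."""
    tree = hierarchy.to_tree(result.linkage)
    names = list(result.assignments.index)

    def walk(node, parent_height):
        length = parent_height - node.dist
        if node.is_leaf():
            return f"{names[node.id]}:{length:.6g}"
        left = walk(node.left, node.dist)
        right = walk(node.right, node.dist)
        return f"({left},{right}):{length:.6g}"

    return walk(tree, tree.dist) + ";"
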