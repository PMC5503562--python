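"""Normalization and the proliferative index (PI).

The PI of a sample is the median normalized expression of a proliferation gene
set (canonically the 131-gene metaPCNA set: the genes most positively
correlated with PCNA across healthy tissues).  Cross-cohort comparisons use
counts-per-million; within-cohort survival analyses use a variance-stabilizing
transform.  The VST here is the documented stand-in ``log2(count/size_factor
+ 1)`` with median-of-ratios size factors — monotone per sample and
variance-stabilizing for negative-binomial counts at moderate means; an
externally computed VST table can be substituted via
:func:`expression_from_table`.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import ExpressionMatrix, GeneSet, ValidationError


@dataclass
class PIVector:
    """Per-sample proliferative index values and their provenance."""

    values: pd.Series              # indexed by sample_id
    normalization: str
    gene_set_name: str
    n_genes_used: int

    @property
    def sample_ids(self) -> list[str]:
        return self.values.index.tolist()

    def reindex(self, sample_ids) -> "PIVector":
        return PIVector(self.values.loc[list(sample_ids)], self.normalization,
                        self.gene_set_name, self.n_genes_used)


@dataclass
class GroupComparison:
    """Two-sided Wilcoxon rank-sum comparison of PI between two groups."""

    group_a: str
    group_b: str
    statistic: float               # Mann-Whitney U for group A
    p_value: float
    median_a: float
    median_b: float
    n_a: int
    n_b: int
    method: str                    # "exact" or "asymptotic"


def cpm_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Scale every sample to one million counts."""
    if expr.normalization != "raw_counts":
        raise ValidationError("cpm_normalize expects raw counts")
    totals = expr.data.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValidationError(f"sample {zero[0]!r} has zero total counts")
    return ExpressionMatrix(expr.data * (1e6 / totals), "cpm")


def vst_normalize(expr: ExpressionMatrix) -> ExpressionMatrix:
    """Variance-stabilize counts: log2(count / size_factor + 1).

    Size factors are DESeq-style median-of-ratios computed over genes with
    all-positive counts; if no such gene exists the library-size factors
    (column total / geometric mean of totals) are used with a warning.
    """
    if expr.normalization != "raw_counts":
        raise ValidationError("vst_normalize expects raw counts")
    if expr.n_samples < 2:
        raise ValidationError("vst_normalize needs at least 2 samples")
    counts = expr.data.to_numpy(dtype=float)
    positive = (counts > 0).all(axis=1)
    if positive.any():
        logc = np.log(counts[positive])
        log_geomean = logc.mean(axis=1)
        ratios = np.exp(logc - log_geomean[:, None])
        size_factors = np.median(ratios, axis=0)
    else:
        warnings.warn("no gene with all-positive counts; falling back to "
                      "library-size factors", stacklevel=2)
        totals = counts.sum(axis=0)
        if (totals == 0).any():
            raise ValidationError("sample with zero total counts")
        size_factors = totals / np.exp(np.mean(np.log(totals)))
    out = np.log2(counts / size_factors[None, :] + 1.0)
    return ExpressionMatrix(pd.DataFrame(out, index=expr.data.index,
                                         columns=expr.data.columns), "vst")


def compute_pi(expr: ExpressionMatrix, genes: GeneSet) -> PIVector:
    """Per-sample PI = median normalized expression of the gene-set genes present.

    Set genes absent from the matrix are dropped (their number is reported via
    ``n_genes_used``); zero matched genes is an error.
    """
    if expr.normalization not in ("cpm", "vst", "scaled"):
        raise ValidationError("compute_pi expects normalized expression (cpm/vst)")
    present = [g for g in genes if g in expr.data.index]
    if not present:
        missing = list(genes)[:5]
        raise ValidationError(
            f"no gene of set {genes.name!r} found in the matrix (first missing: {missing})")
    pi = expr.data.loc[present].median(axis=0)
    pi.name = "pi"
    return PIVector(pi, expr.normalization, genes.name, len(present))


def compare_pi_groups(pi: PIVector, labels: pd.Series, a: str, b: str) -> GroupComparison:
    """Two-sided Wilcoxon rank-sum test of PI between label groups ``a`` and ``b``.

    Exact null distribution when the combined n is at most 20 and there are no
    ties; normal approximation with continuity correction otherwise.
    """
    labels = labels.reindex(pi.values.index)
    xa = pi.values[labels == a].to_numpy()
    xb = pi.values[labels == b].to_numpy()
    if len(xa) == 0 or len(xb) == 0:
        raise ValidationError(f"empty group: {a if len(xa) == 0 else b!r}")
    pooled = np.concatenate([xa, xb])
    no_ties = len(np.unique(pooled)) == len(pooled)
    method = "exact" if (len(pooled) <= 20 and no_ties) else "asymptotic"
    res = stats.mannwhitneyu(xa, xb, alternative="two-sided", method=method,
                             use_continuity=True)
    return GroupComparison(a, b, float(res.statistic), float(res.pvalue),
                           float(np.median(xa)), float(np.median(xb)),
                           len(xa), len(xb), method)


def pc_pi_correlation(expr: ExpressionMatrix, pi: PIVector, k: int) -> pd.Series:
    """Spearman rho between each of the first ``k`` principal-component sample
    scores and PI.

    PCA centers genes across samples; sample scores come from the SVD of the
    centered genes x samples matrix.
    """
    if expr.normalization != "vst":
        raise ValidationError("pc_pi_correlation expects VST expression")
    if k > min(expr.n_genes, expr.n_samples):
        raise ValidationError("k exceeds matrix rank bound")
    x = expr.data.to_numpy(dtype=float)
    x = x - x.mean(axis=1, keepdims=True)
    if not np.any(x):
        raise ValidationError("constant expression matrix has no principal components")
    _, s, vt = np.linalg.svd(x, full_matrices=False)
    scores = vt[:k].T * s[:k]      # samples x k
    piv = pi.reindex(expr.sample_ids).values.to_numpy()
    rho = [stats.spearmanr(scores[:, j], piv).statistic for j in range(k)]
    return pd.Series(rho, index=[f"PC{j + 1}" for j in range(k)], name="spearman_rho")


def correlate_pi_covariate(pi: PIVector, covariate: pd.Series):
    """Spearman rank correlation (tie-corrected, two-sided p) of PI against a
    numeric per-sample covariate; returns ``(rho, p, n)``."""
    joined = pd.concat([pi.values, covariate], axis=1, join="inner").dropna()
    if len(joined) < 3:
        raise ValidationError("need at least 3 paired observations")
    cov = joined.iloc[:, 1].to_numpy()
    if np.all(cov == cov[0]):
        warnings.warn("constant covariate: Spearman rho undefined", stacklevel=2)
        return float("nan"), float("nan"), len(joined)
    res = stats.spearmanr(joined.iloc[:, 0], joined.iloc[:, 1])
    return float(res.statistic), float(res.pvalue), len(joined)


def expression_from_table(table: pd.DataFrame, normalization: str) -> ExpressionMatrix:
    """Adapter seam: wrap an externally normalized genes x samples table (e.g. a
    VST computed by a reference implementation) for downstream use."""
    return ExpressionMatrix(table, normalization)
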