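"""Convenience drivers wiring the per-module operations into the full analysis."""

from __future__ import annotations

import pandas as pd

from .io import ExpressionMatrix, GeneSet, filter_cohorts
from .index import PIVector, vst_normalize, cpm_normalize, compute_pi
from .survival import (pi_survival_scan, transcriptome_survival_scan,
                       select_shared_transcripts, cluster_cancers, identify_pics)


def split_expression_by_cancer(expr: ExpressionMatrix,
                               cohort: pd.DataFrame) -> dict[str, ExpressionMatrix]:
    """Per-cancer raw-count submatrices restricted to cohort samples."""
    return {cancer: expr.subset_samples(sub["sample_id"])
            for cancer, sub in cohort.groupby("cancer_type", sort=False)}


def per_cancer_vst(expr: ExpressionMatrix,
                   cohort: pd.DataFrame) -> dict[str, ExpressionMatrix]:
    """Variance-stabilize each cancer's counts independently (intra-cancer scale)."""
    return {cancer: vst_normalize(sub)
            for cancer, sub in split_expression_by_cancer(expr, cohort).items()}


def per_cancer_pi(expr_by_cancer: dict[str, ExpressionMatrix],
                  genes: GeneSet) -> dict[str, PIVector]:
    return {cancer: compute_pi(e, genes) for cancer, e in expr_by_cancer.items()}


def pooled_cpm_pi(expr: ExpressionMatrix, genes: GeneSet) -> PIVector:
    """Cross-cancer comparable PI: CPM-normalize the pooled matrix, then PI."""
    return compute_pi(cpm_normalize(expr), genes)


def survival_analysis(expr: ExpressionMatrix, cohort: pd.DataFrame, genes: GeneSet,
                      min_patients: int = 50, min_deaths: int = 25,
                      alpha: float = 0.05, shared_min_cancers: int = 9):
    """Cohort filter -> per-cancer VST -> PI scan -> PIC labels -> transcriptome
    scan -> shared transcripts -> cancer clustering.

    Returns a dict with the intermediate products keyed by stage name.
    """
    cohort = filter_cohorts(cohort, min_patients, min_deaths)
    vst = per_cancer_vst(expr, cohort)
    pi = per_cancer_pi(vst, genes)
    scan = pi_survival_scan(cohort, pi)
    labels = identify_pics(scan, n_cancers=len(scan.table), alpha=alpha)
    pmat = transcriptome_survival_scan(cohort, vst)
    shared = select_shared_transcripts(pmat, alpha=alpha,
                                       min_cancers=shared_min_cancers)
    clusters = cluster_cancers(pmat, shared) if len(shared) else None
    return {"cohort": cohort, "vst": vst, "pi": pi, "labels": labels,
            "pmat": pmat, "shared": shared, "clusters": clusters}
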