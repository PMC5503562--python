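"""PI versus somatic mutation burden, per-gene mutation status, and drug response.

Burden association is the Spearman correlation between PI and the log10 total
mutation count per patient (all variant classes; a +1 pseudocount retains
zero-mutation patients — Spearman depends only on ranks, so any monotone
handling that keeps them lowest is equivalent).  Per-gene associations contrast
PI between carriers of a missense/nonsense mutation and patients with only
synonymous or no mutation in that gene; carriers of only "other"-class variants
are excluded from both groups.  Cross-cancer evidence is pooled with Fisher's
combined chi-square and controlled with Benjamini-Hochberg FDR.

Cell-line PI is the median normalized expression over probes mapping to PI
genes; drug response associations are Spearman correlations with EC50.
Connectivity-style rank matrices are scored by the median rank of PI probes per
treatment: treatments that up-regulate the proliferation program have small
median ranks and land at high activation percentiles, anti-proliferative
treatments at low ones.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneSet, ValidationError
from .index import PIVector

logger = logging.getLogger(__name__)

PROTEIN_ALTERING = ("missense", "nonsense")


@dataclass
class DrugResponsePanel:
    """Cell lines x drugs EC50 table with matching probe-level expression."""

    ec50: pd.DataFrame             # lines x drugs, positive concentrations
    expression: pd.DataFrame       # probes x lines, normalized
    probe_gene: pd.Series          # probe -> gene symbol

    def __post_init__(self) -> None:
        if (self.ec50.to_numpy() <= 0).any():
            raise ValidationError("EC50 values must be positive")
        if not set(self.ec50.index) & set(self.expression.columns):
            raise ValidationError("no cell line shared between EC50 and expression tables")


@dataclass
class TreatmentRankMatrix:
    """Probe x treatment integer rank matrix (1 = strongest up-regulation)."""

    ranks: pd.DataFrame
    probe_gene: pd.Series

    def __post_init__(self) -> None:
        p = self.ranks.shape[0]
        expected = np.arange(1, p + 1)
        arr = np.sort(self.ranks.to_numpy(), axis=0)
        if not (arr == expected[:, None]).all():
            raise ValidationError("every rank column must be a permutation of 1..P")


def mutation_burden_correlation(pi: PIVector, catalog: pd.DataFrame,
                                cohort: pd.DataFrame | None = None,
                                scope: str = "pooled"):
    """Spearman correlation between PI and log10(total mutations + 1).

    ``scope="pooled"`` returns one ``(rho, p, n)`` triple over all patients with
    both PI and mutation data (zero-mutation patients retained at count 0);
    ``scope="per_cancer"`` returns a DataFrame with one row per cancer and
    requires ``cohort`` for the sample -> cancer map.
    """
    counts = catalog.groupby("sample_id").size()
    burden = np.log10(counts.reindex(pi.values.index).fillna(0) + 1.0)
    paired = pd.DataFrame({"pi": pi.values, "burden": burden}).dropna()
    if scope == "pooled":
        if len(paired) < 3:
            raise ValidationError("fewer than 3 patients with both PI and mutation data")
        res = stats.spearmanr(paired["pi"], paired["burden"])
        return float(res.statistic), float(res.pvalue), len(paired)
    if scope != "per_cancer":
        raise ValueError(f"unknown scope {scope!r}")
    if cohort is None:
        raise ValidationError("per_cancer scope requires a cohort table")
    cancer_of = cohort.set_index("sample_id")["cancer_type"]
    paired["cancer"] = cancer_of.reindex(paired.index)
    rows = {}
    for cancer, sub in paired.groupby("cancer"):
        if len(sub) < 3:
            warnings.warn(f"{cancer}: fewer than 3 paired patients; skipped", stacklevel=2)
            continue
        res = stats.spearmanr(sub["pi"], sub["burden"])
        rows[cancer] = {"rho": float(res.statistic), "p_value": float(res.pvalue),
                        "n": len(sub)}
    return pd.DataFrame.from_dict(rows, orient="index")


def _class_flags(muts: pd.DataFrame) -> pd.DataFrame:
    """Per (gene, sample) booleans: carries protein-altering / synonymous /
    other-class variants."""
    pairs = muts.drop_duplicates(["gene", "sample_id", "variant_class"])
    flags = (pairs.assign(v=True)
             .pivot_table(index=["gene", "sample_id"], columns="variant_class",
                          values="v", aggfunc="any", fill_value=False))
    for cls in ("missense", "nonsense", "synonymous", "other"):
        if cls not in flags.columns:
            flags[cls] = False
    out = pd.DataFrame(index=flags.index)
    out["qualifying"] = flags["missense"] | flags["nonsense"]
    out["synonymous"] = flags["synonymous"]
    out["other"] = flags["other"]
    return out


def gene_mutation_scan(pi_by_cancer: dict[str, PIVector], catalog: pd.DataFrame,
                       min_mutated: int = 5, min_genes: int = 100):
    """Per-gene Wilcoxon tests of PI by mutation status, combined across cancers.

    Within each cancer, genes with at least ``min_mutated`` samples carrying a
    missense/nonsense mutation are tested (two-sided Wilcoxon of PI, carriers vs
    synonymous-or-unmutated; "other"-only carriers excluded from both groups).
    Cancers with fewer than ``min_genes`` eligible genes are skipped entirely.
    Genes tested in at least 2 cancers get a Fisher's combined chi-square and a
    Benjamini-Hochberg q-value.

    Returns ``(combined, per_cancer)`` DataFrames.
    """
    per_cancer_rows = []
    for cancer, pi in pi_by_cancer.items():
        samples = pi.values.index
        muts = catalog[catalog["sample_id"].isin(samples)]
        if muts.empty:
            logger.info("%s skipped: no mutations", cancer)
            continue
        flags = _class_flags(muts)
        carriers = flags[flags["qualifying"]].reset_index().groupby("gene")[
            "sample_id"].agg(list)
        other_only = (flags[~flags["qualifying"] & ~flags["synonymous"]
                            & flags["other"]]
                      .reset_index().groupby("gene")["sample_id"].agg(list))
        eligible = carriers.index[(carriers.map(len) >= min_mutated)
                                  & (carriers.map(len) < len(samples))]
        if len(eligible) < min_genes:
            logger.info("%s skipped: only %d genes with >= %d qualifying mutations",
                        cancer, len(eligible), min_mutated)
            continue
        pi_vals = pi.values
        for gene in eligible:
            mutated = pd.Index(carriers[gene])
            excluded = pd.Index(other_only.get(gene, [])).difference(mutated)
            wild = samples.difference(mutated).difference(excluded)
            if len(wild) == 0:
                continue
            a = pi_vals.loc[mutated]
            b = pi_vals.loc[wild]
            res = stats.mannwhitneyu(a, b, alternative="two-sided")
            per_cancer_rows.append({
                "gene": gene, "cancer": cancer, "p_value": float(res.pvalue),
                "direction": float(np.sign(a.median() - b.median())),
                "n_mutated": len(mutated), "n_wildtype": len(wild),
                "n_excluded": len(excluded)})
    per_cancer = pd.DataFrame(per_cancer_rows)
    if per_cancer.empty:
        return pd.DataFrame(), per_cancer

    combined_rows = []
    for gene, sub in per_cancer.groupby("gene", sort=False):
        if len(sub) < 2:
            continue
        chi2, p = fisher_combine(sub["p_value"].tolist())
        combined_rows.append({"gene": gene, "chi2": chi2, "p_combined": p,
                              "n_cancers": len(sub),
                              "mean_direction": float(sub["direction"].mean())})
    combined = pd.DataFrame(combined_rows)
    if not combined.empty:
        combined["q_value"] = fdr_adjust(combined["p_combined"].to_numpy())
        combined = combined.sort_values("p_combined").reset_index(drop=True)
    return combined, per_cancer


def fisher_combine(p_values) -> tuple[float, float]:
    """Fisher's combined probability: chi2 = -2 sum(ln p), df = 2k."""
    p = np.asarray(p_values, dtype=float)
    if len(p) < 2:
        raise ValidationError("fisher_combine needs at least 2 p-values")
    if (p <= 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in (0, 1]")
    chi2 = float(-2.0 * np.sum(np.log(p)))
    return chi2, float(stats.chi2.sf(chi2, df=2 * len(p)))


def fdr_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values."""
    return stats.false_discovery_control(np.asarray(p_values, dtype=float), method="bh")


def drug_ec50_correlation(panel: DrugResponsePanel, genes: GeneSet,
                          min_lines: int = 10) -> pd.DataFrame:
    """Per-drug Spearman correlation between cell-line PI and EC50, with BH q.

    Line PI = median expression over probes mapping to PI-set genes.
    """
    pi_probes = panel.probe_gene.index[panel.probe_gene.isin(genes.genes)]
    if len(pi_probes) == 0:
        raise ValidationError(f"no probe maps to a gene of set {genes.name!r}")
    line_pi = panel.expression.loc[pi_probes].median(axis=0)
    rows = []
    for drug in panel.ec50.columns:
        paired = pd.DataFrame({"pi": line_pi, "ec50": panel.ec50[drug]}).dropna()
        if len(paired) < min_lines:
            warnings.warn(f"{drug}: fewer than {min_lines} lines; skipped", stacklevel=2)
            continue
        res = stats.spearmanr(paired["pi"], paired["ec50"])
        rows.append({"drug": drug, "rho": float(res.statistic),
                     "p_value": float(res.pvalue), "n": len(paired)})
    out = pd.DataFrame(rows)
    if not out.empty:
        out["q_value"] = fdr_adjust(out["p_value"].to_numpy())
    return out


def cmap_pi_rank(rank_matrix: TreatmentRankMatrix, genes: GeneSet) -> pd.DataFrame:
    """Median PI-probe rank and activation percentile per treatment.

    A treatment's activation percentile is the fraction of treatments with a
    numerically larger median PI rank (i.e. that up-regulate the proliferation
    program less): PI-activating treatments score near 1 ("top"), strongly
    anti-proliferative treatments near 0 ("bottom decile").
    """
    pi_probes = rank_matrix.probe_gene.index[
        rank_matrix.probe_gene.isin(genes.genes)]
    pi_probes = [p for p in pi_probes if p in rank_matrix.ranks.index]
    if not pi_probes:
        raise ValidationError(f"no PI probe of set {genes.name!r} in the rank matrix")
    med = rank_matrix.ranks.loc[pi_probes].median(axis=0)
    n = len(med)
    percentile = med.map(lambda m: float((med > m).sum()) / n)
    return pd.DataFrame({"median_rank": med, "percentile": percentile})


def cmap_compare_treatments(rank_matrix: TreatmentRankMatrix, genes: GeneSet,
                            treatment_a: str, treatment_b: str):
    """Kolmogorov-Smirnov comparison of two treatments' full PI-probe rank
    distributions; returns ``(ks_statistic, p)``."""
    pi_probes = rank_matrix.probe_gene.index[
        rank_matrix.probe_gene.isin(genes.genes)]
    pi_probes = [p for p in pi_probes if p in rank_matrix.ranks.index]
    if not pi_probes:
        raise ValidationError("no PI probe in the rank matrix")
    a = rank_matrix.ranks.loc[pi_probes, treatment_a]
    b = rank_matrix.ranks.loc[pi_probes, treatment_b]
    if a.equals(b):
        return 0.0, 1.0
    res = stats.ks_2samp(a, b)
    return float(res.statistic), float(res.pvalue)
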