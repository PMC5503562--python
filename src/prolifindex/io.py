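"""Readers, writers, and validated containers for the tabular formats the pipeline touches.

Expression matrices are tab-separated with genes in rows and samples in columns
(the TCGA Level 3 convention); composite ``symbol|entrez`` row keys are split on
``|`` and the symbol kept.  Clinical tables are per-patient TSVs carrying overall
survival, vital status, and pathologic T/N/M stage.  Mutation tables are MAF-like
(sample, gene, variant classification).  All round-trip exactly through
:func:`write_expression` / :func:`write_clinical`.
"""

from __future__ import annotations

import logging
import re
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

NORMALIZATIONS = ("raw_counts", "cpm", "vst", "scaled")

#: closed variant-class vocabulary used by the mutation association analyses
VARIANT_CLASSES = ("missense", "nonsense", "synonymous", "other")

_VARIANT_MAP = {
    "missense_mutation": "missense",
    "missense": "missense",
    "nonsense_mutation": "nonsense",
    "nonsense": "nonsense",
    "silent": "synonymous",
    "synonymous": "synonymous",
}

CLINICAL_COLUMNS = ["sample_id", "cancer_type", "survival_days", "event",
                    "stage_T", "stage_N", "stage_M", "subtype", "purity"]


class FormatError(ValueError):
    """A file does not follow the expected dialect."""


class ValidationError(ValueError):
    """Parsed content violates a domain invariant."""


@dataclass
class ExpressionMatrix:
    """Genes x samples numeric matrix plus its normalization state."""

    data: pd.DataFrame
    normalization: str = "raw_counts"

    def __post_init__(self) -> None:
        if self.normalization not in NORMALIZATIONS:
            raise ValidationError(f"unknown normalization {self.normalization!r}")
        if self.data.index.has_duplicates:
            dupes = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate gene ids after collapse: {dupes[:5]}")
        if self.normalization == "raw_counts" and (self.data.to_numpy() < 0).any():
            raise ValidationError("raw counts must be nonnegative")

    @property
    def gene_ids(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    @property
    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_genes(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def subset_samples(self, sample_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(self.data.loc[:, list(sample_ids)], self.normalization)


@dataclass
class GeneSet:
    """Named list of unique gene symbols (e.g. the 131-gene metaPCNA set).

    User-supplied sets must be nonempty; selections computed by the pipeline
    may legitimately come back empty (``allow_empty=True``).
    """

    name: str
    genes: list[str]
    allow_empty: bool = False

    def __post_init__(self) -> None:
        if not self.genes and not self.allow_empty:
            raise ValidationError(f"gene set {self.name!r} is empty")
        if len(set(self.genes)) != len(self.genes):
            raise ValidationError(f"gene set {self.name!r} contains duplicates")

    def __len__(self) -> int:
        return len(self.genes)

    def __iter__(self):
        return iter(self.genes)


@dataclass
class RunConfig:
    """Run-level thresholds and bookkeeping shared by the CLI subcommands."""

    min_patients: int = 50
    min_deaths: int = 25
    alpha: float = 0.05
    shared_min_cancers: int = 9
    dichotomy_k: int = 18
    n_permutations: int = 1000
    permutation_set_size: int = 7
    seed: int = 0
    paths: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("min_patients", "min_deaths", "shared_min_cancers",
                     "dichotomy_k", "n_permutations", "permutation_set_size"):
            if getattr(self, name) <= 0:
                raise ValidationError(f"{name} must be positive")
        if not 0 < self.alpha < 1:
            raise ValidationError("alpha must lie in (0,1)")


# ---------------------------------------------------------------------------
# expression


def read_expression(path, collapse: str = "sum") -> ExpressionMatrix:
    """Load a genes-x-samples count TSV.

    Composite ``symbol|entrez`` gene ids are split on ``|`` and the symbol kept.
    Duplicate gene rows are collapsed with ``collapse`` (``sum`` by default —
    counts are additive over features; also ``mean`` or ``first``).
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", index_col=0, dtype=str,
                         keep_default_na=False, na_values=[])
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty expression file") from exc
    if df.shape[1] == 0:
        raise FormatError(f"{path}: no sample columns found")

    genes = [str(g).split("|")[0] for g in df.index]
    df.index = pd.Index(genes, name="gene")

    numeric = df.apply(pd.to_numeric, errors="coerce")
    if numeric.isna().any().any():
        mask = numeric.isna()
        row = mask.any(axis=1).idxmax()
        col = mask.loc[row].idxmax()
        raise FormatError(
            f"{path}: non-numeric value {df.loc[row, col]!r} at gene {row!r}, sample {col!r}")

    if numeric.index.has_duplicates:
        if collapse == "sum":
            numeric = numeric.groupby(level=0, sort=False).sum()
        elif collapse == "mean":
            numeric = numeric.groupby(level=0, sort=False).mean()
        elif collapse == "first":
            numeric = numeric[~numeric.index.duplicated(keep="first")]
        else:
            raise ValueError(f"unknown collapse mode {collapse!r}")
    return ExpressionMatrix(numeric, "raw_counts")


def write_expression(expr: ExpressionMatrix, path) -> None:
    expr.data.to_csv(path, sep="\t", index_label="gene")


# ---------------------------------------------------------------------------
# clinical

_STAGE_RE = re.compile(r"^([TNM])(\d+)", re.IGNORECASE)


def _ordinal_stage(value, axis: str):
    """Map a pathologic stage string to its whole-stage ordinal (``T1b`` -> ``T1``)."""
    if value is None or (isinstance(value, float) and np.isnan(value)):
        return np.nan
    s = str(value).strip()
    if s == "" or s.upper() in {"NA", "NAN", "NONE"}:
        return np.nan
    m = _STAGE_RE.match(s)
    if m is None or m.group(1).upper() != axis:
        return np.nan
    return f"{axis}{int(m.group(2))}"


def _parse_event(value):
    s = str(value).strip().lower()
    if s in {"1", "true", "dead", "deceased"}:
        return True
    if s in {"0", "false", "alive", "living"}:
        return False
    raise ValidationError(f"unknown event code {value!r} (expected 0/1 style)")


def read_clinical(path) -> pd.DataFrame:
    """Load a per-patient clinical TSV into a cohort table.

    Required: ``sample_id``, ``cancer_type``, ``event`` and either a
    ``survival_days`` column or ``days_to_death``/``days_to_last_followup``
    columns, in which case overall survival is the row-wise maximum of the two.
    Stage strings are reduced to whole-stage ordinals; missing stays missing.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str, keep_default_na=False, na_values=["", "NA"])
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty clinical file") from exc
    for col in ("sample_id", "cancer_type"):
        if col not in df.columns:
            raise FormatError(f"{path}: missing required column {col!r}")
    if "event" not in df.columns:
        raise FormatError(f"{path}: missing required column 'event'")

    out = pd.DataFrame({"sample_id": df["sample_id"].astype(str),
                        "cancer_type": df["cancer_type"].astype(str)})

    if "survival_days" in df.columns:
        out["survival_days"] = pd.to_numeric(df["survival_days"], errors="raise")
    else:
        parts = []
        for col in ("days_to_death", "days_to_last_followup"):
            if col in df.columns:
                parts.append(pd.to_numeric(df[col], errors="coerce"))
        if not parts:
            raise FormatError(f"{path}: no survival_days or days_to_* columns")
        out["survival_days"] = pd.concat(parts, axis=1).max(axis=1)
    if out["survival_days"].isna().any():
        raise ValidationError(f"{path}: missing survival time for "
                              f"{out.loc[out['survival_days'].isna(), 'sample_id'].iloc[0]!r}")
    if (out["survival_days"] < 0).any():
        bad = out.loc[out["survival_days"] < 0, "sample_id"].iloc[0]
        raise ValidationError(f"{path}: negative survival_days for sample {bad!r}")

    out["event"] = df["event"].map(_parse_event)

    for axis, col in (("T", "stage_T"), ("N", "stage_N"), ("M", "stage_M")):
        src = None
        for cand in (col, f"pathologic_{axis}"):
            if cand in df.columns:
                src = cand
                break
        out[col] = (df[src].map(lambda v: _ordinal_stage(v, axis))
                    if src is not None else np.nan)

    out["subtype"] = df["subtype"] if "subtype" in df.columns else np.nan
    out["purity"] = (pd.to_numeric(df["purity"], errors="coerce")
                     if "purity" in df.columns else np.nan)

    return validate_cohort(out)


def validate_cohort(cohort: pd.DataFrame) -> pd.DataFrame:
    """Check cohort-table invariants; returns the (unmodified) table."""
    dup = cohort.duplicated(subset=["cancer_type", "sample_id"])
    if dup.any():
        raise ValidationError(
            f"duplicate sample within a cancer: {cohort.loc[dup, 'sample_id'].iloc[0]!r}")
    if (cohort["survival_days"] < 0).any():
        raise ValidationError("negative survival_days")
    if not cohort["event"].map(lambda v: isinstance(v, (bool, np.bool_))).all():
        raise ValidationError("event column must be boolean")
    n_zero = int((cohort["survival_days"] == 0).sum())
    if n_zero:
        logger.warning("%d patients with 0-day survival retained", n_zero)
    return cohort


def write_clinical(cohort: pd.DataFrame, path) -> None:
    out = cohort.copy()
    out["event"] = out["event"].astype(int)
    out.to_csv(path, sep="\t", index=False)


def filter_cohorts(cohort: pd.DataFrame, min_patients: int = 50,
                   min_deaths: int = 25) -> pd.DataFrame:
    """Keep cancer types with at least ``min_patients`` patients of whom at
    least ``min_deaths`` died (uncensored survival information).

    Idempotent; an all-cancers-removed result is a warning, not an error.
    """
    stats = cohort.groupby("cancer_type").agg(
        n=("sample_id", "size"), deaths=("event", "sum"))
    keep = stats.index[(stats["n"] >= min_patients) & (stats["deaths"] >= min_deaths)]
    out = cohort[cohort["cancer_type"].isin(keep)].reset_index(drop=True)
    if out.empty and not cohort.empty:
        warnings.warn("cohort filter removed every cancer type", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# gene sets / mutations / drug tables


def read_gene_set(path, name: str | None = None) -> GeneSet:
    """Read a one-symbol-per-line gene list; '#' comments and blanks ignored."""
    path = Path(path)
    genes: list[str] = []
    seen = set()
    for line in path.read_text().splitlines():
        sym = line.split("#")[0].strip()
        if not sym:
            continue
        if sym in seen:
            warnings.warn(f"duplicate gene {sym!r} in {path.name} ignored", stacklevel=2)
            continue
        seen.add(sym)
        genes.append(sym)
    if not genes:
        raise FormatError(f"{path}: no gene symbols found")
    return GeneSet(name or path.stem, genes)


def write_gene_set(genes: GeneSet, path) -> None:
    Path(path).write_text("\n".join(genes.genes) + "\n")


def read_mutations(path) -> pd.DataFrame:
    """Load a MAF-like TSV into a mutation catalog.

    Accepts ``sample_id``/``Tumor_Sample_Barcode``, ``gene``/``Hugo_Symbol`` and
    ``variant_class``/``Variant_Classification`` headers.  Classifications
    outside the closed {missense, nonsense, synonymous} vocabulary map to
    ``other`` with a logged warning.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path, sep="\t", dtype=str)
    except pd.errors.EmptyDataError as exc:
        raise FormatError(f"{path}: empty mutation file") from exc

    def pick(*names):
        for n in names:
            if n in df.columns:
                return n
        raise FormatError(f"{path}: need one of columns {names}")

    out = pd.DataFrame({
        "sample_id": df[pick("sample_id", "Tumor_Sample_Barcode", "sample")].astype(str),
        "gene": df[pick("gene", "Hugo_Symbol")].astype(str),
    })
    raw = df[pick("variant_class", "Variant_Classification", "variant_classification")]
    mapped = raw.str.strip().str.lower().map(_VARIANT_MAP)
    unknown = raw[mapped.isna()].unique()
    if len(unknown):
        logger.warning("unmapped variant classifications recorded as 'other': %s",
                       ", ".join(map(str, unknown[:10])))
    out["variant_class"] = mapped.fillna("other")
    return out


def write_mutations(catalog: pd.DataFrame, path) -> None:
    catalog.to_csv(path, sep="\t", index=False)


def read_rank_matrix(path) -> pd.DataFrame:
    """Read a CMap-style probe x treatment integer rank matrix.

    Each column must be a permutation of ``1..P`` (rank 1 = largest positive
    expression change after treatment).
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t", index_col=0)
    p = df.shape[0]
    expected = np.arange(1, p + 1)
    arr = df.to_numpy()
    for j, col in enumerate(df.columns):
        if not np.array_equal(np.sort(arr[:, j]), expected):
            raise FormatError(f"{path}: column {col!r} is not a permutation of 1..{p}")
    return df.astype(int)


def read_probe_map(path) -> pd.Series:
    """Read a two-column probe -> gene TSV into a Series indexed by probe."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if df.shape[1] < 2:
        raise FormatError(f"{path}: expected probe and gene columns")
    return pd.Series(df.iloc[:, 1].values, index=df.iloc[:, 0].values, name="gene")


def read_drug_response(path) -> pd.DataFrame:
    """Read a long-format (line, drug, EC50) table into a lines x drugs matrix."""
    sep = "," if str(path).endswith(".csv") else "\t"
    df = pd.read_csv(path, sep=sep)
    cols = {c.lower(): c for c in df.columns}
    try:
        line_c, drug_c, ec_c = cols["line"], cols["drug"], cols["ec50"]
    except KeyError as exc:
        raise FormatError(f"{path}: need columns line, drug, ec50") from exc
    wide = df.pivot_table(index=line_c, columns=drug_c, values=ec_c, aggfunc="first")
    if (wide.to_numpy() <= 0).any():
        raise ValidationError(f"{path}: EC50 values must be positive")
    return wide
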