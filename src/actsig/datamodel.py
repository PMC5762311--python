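"""Shared data model for multi-layer tumor cohort data.

The central container is a :class:`CohortBundle` holding aligned
expression, copy-number, mutation and miRNA layers plus a clinical table,
all keyed by sample ID.  Expression matrices are genes x samples on log2
scale; copy number is gene-level thresholded GISTIC (-2..2); mutations are
binary gene x sample indicators.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "GeneExpressionMatrix",
    "CopyNumberMatrix",
    "MutationMatrix",
    "MiRNAMatrix",
    "ClinicalTable",
    "CohortBundle",
    "GeneSet",
    "standardize_genes",
    "align_cohort",
    "match_signature_genes",
]

GISTIC_LEVELS = (-2, -1, 0, 1, 2)

CLINICAL_COLUMNS = [
    "os_time", "os_event", "dfs_time", "dfs_event", "hpv_status", "sex",
    "age", "anatomic_site", "t_stage", "n_stage", "overall_stage",
    "radiation", "cohort_name",
]


def _check_unique(ids: Sequence[str], what: str) -> None:
    if len(set(ids)) != len(ids):
        dupes = pd.Index(ids)[pd.Index(ids).duplicated()].unique().tolist()
        raise ValueError(f"duplicate {what}: {dupes[:5]}")


@dataclass
class GeneExpressionMatrix:
    """Gene-level log2 expression, genes in rows, samples in columns."""

    values: pd.DataFrame
    standardized: bool = False

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "gene_ids")
        _check_unique(self.values.columns, "sample_ids")
        if not np.isfinite(self.values.to_numpy(dtype=float)).all():
            raise ValueError("expression matrix contains non-finite values")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "GeneExpressionMatrix":
        return GeneExpressionMatrix(self.values[list(sample_ids)], self.standardized)


@dataclass
class CopyNumberMatrix:
    """Thresholded GISTIC scores per gene and sample (integers in -2..2)."""

    scores: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.scores.index, "gene_ids")
        _check_unique(self.scores.columns, "sample_ids")
        arr = self.scores.to_numpy()
        if not np.isin(arr, GISTIC_LEVELS).all():
            bad = sorted(set(arr.ravel()) - set(GISTIC_LEVELS))
            raise ValueError(f"GISTIC scores outside {{-2..2}}: {bad[:5]}")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.scores.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.scores.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "CopyNumberMatrix":
        return CopyNumberMatrix(self.scores[list(sample_ids)])


@dataclass
class MutationMatrix:
    """Binary indicator of any non-silent somatic mutation per gene/sample."""

    mutated: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.mutated.index, "gene_ids")
        _check_unique(self.mutated.columns, "sample_ids")
        arr = self.mutated.to_numpy()
        if not np.isin(arr, (0, 1)).all():
            raise ValueError("mutation matrix must be binary")

    @property
    def gene_ids(self) -> list[str]:
        return list(self.mutated.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.mutated.columns)

    def subset_samples(self, sample_ids: Sequence[str]) -> "MutationMatrix":
        return MutationMatrix(self.mutated[list(sample_ids)])


@dataclass
class MiRNAMatrix:
    """log2 miRNA expression; samples labelled tumor or normal.

    Normal-tissue columns participate only in the tumor-vs-normal stages of
    the miRNA screens and carry no clinical annotation.
    """

    values: pd.DataFrame
    sample_class: pd.Series  # "tumor" / "normal" per column

    def __post_init__(self) -> None:
        _check_unique(self.values.index, "mirna_ids")
        _check_unique(self.values.columns, "sample_ids")
        self.sample_class = self.sample_class.reindex(self.values.columns)
        bad = set(self.sample_class.dropna().unique()) - {"tumor", "normal"}
        if bad or self.sample_class.isna().any():
            raise ValueError("sample_class must label every sample tumor/normal")

    @property
    def mirna_ids(self) -> list[str]:
        return list(self.values.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.values.columns)

    @property
    def tumor_ids(self) -> list[str]:
        return list(self.sample_class[self.sample_class == "tumor"].index)

    @property
    def normal_ids(self) -> list[str]:
        return list(self.sample_class[self.sample_class == "normal"].index)

    def subset_tumors(self, sample_ids: Sequence[str]) -> "MiRNAMatrix":
        """Restrict tumor columns to ``sample_ids``; normals always kept."""
        keep = [s for s in self.sample_ids
                if s in set(sample_ids) or self.sample_class[s] == "normal"]
        return MiRNAMatrix(self.values[keep], self.sample_class[keep])


@dataclass
class ClinicalTable:
    """Per-sample clinical annotation, indexed by sample ID.

    Expected columns: os_time (months), os_event (0/1), optional dfs_time /
    dfs_event, hpv_status in {positive, negative, unknown}, sex, age,
    anatomic_site, t_stage, n_stage, overall_stage, radiation in
    {yes, no, unknown}, cohort_name.  Unknowns are permitted everywhere.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        _check_unique(self.table.index, "sample_ids")
        for col in ("os_time", "dfs_time"):
            if col in self.table.columns:
                t = pd.to_numeric(self.table[col], errors="coerce")
                if (t.dropna() < 0).any():
                    raise ValueError(f"negative {col}")
        for col in ("os_event", "dfs_event"):
            if col in self.table.columns:
                e = self.table[col].dropna()
                if not e.isin([0, 1]).all():
                    raise ValueError(f"{col} must be 0/1")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.table.index)

    def subset_samples(self, sample_ids: Sequence[str]) -> "ClinicalTable":
        return ClinicalTable(self.table.loc[list(sample_ids)])


@dataclass
class CohortBundle:
    """Aligned omics layers plus clinical data for one cohort.

    Every layer's tumor samples are a subset of the clinical table's
    samples; layers may cover fewer samples than the clinical table
    (per-layer n is reported by :func:`align_cohort`).
    """

    name: str
    expression: GeneExpressionMatrix
    clinical: ClinicalTable
    cn: Optional[CopyNumberMatrix] = None
    mutations: Optional[MutationMatrix] = None
    mirna: Optional[MiRNAMatrix] = None

    @property
    def sample_ids(self) -> list[str]:
        return self.expression.sample_ids


@dataclass
class GeneSet:
    """A named, non-empty set of uppercase gene symbols (GMT-serializable)."""

    name: str
    gene_ids: tuple[str, ...]
    description: str = ""

    def __post_init__(self) -> None:
        if len(self.gene_ids) == 0:
            raise ValueError("GeneSet must be non-empty")
        self.gene_ids = tuple(g.upper() for g in self.gene_ids)
        _check_unique(self.gene_ids, "gene_ids")

    def __len__(self) -> int:
        return len(self.gene_ids)

    def __contains__(self, gene: str) -> bool:
        return gene.upper() in set(self.gene_ids)


def standardize_genes(m: GeneExpressionMatrix, force: bool = False) -> GeneExpressionMatrix:
    """Standardize each gene row to mean 0, SD 1 within this cohort.

    SD uses denominator n-1.  Constant rows become all zeros so matrix
    shapes stay stable (they carry no correlation or score information).

    Parameters
    ----------
    m : expression matrix, not already standardized unless ``force``.
    force : re-standardize an already-standardized matrix (a no-op in
        effect, up to floating-point error).
    """
    if m.standardized and not force:
        raise ValueError("matrix already standardized (pass force=True to redo)")
    vals = m.values.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValueError("standardization undefined for a single-sample cohort")
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    out = np.zeros_like(vals)
    nonconst = (sd > 0).ravel()
    out[nonconst] = (vals[nonconst] - mean[nonconst]) / sd[nonconst]
    df = pd.DataFrame(out, index=m.values.index, columns=m.values.columns)
    return GeneExpressionMatrix(df, standardized=True)


def _truncate_ids(ids: Sequence[str], prefix_len: Optional[int]) -> list[str]:
    if prefix_len is None:
        return list(ids)
    return [s[:prefix_len] for s in ids]


def _dedupe_truncated(df: pd.DataFrame, prefix_len: Optional[int], axis: int = 1) -> pd.DataFrame:
    """Truncate sample IDs to a prefix; on collision keep the first column."""
    if prefix_len is None:
        return df
    new = _truncate_ids(df.columns, prefix_len)
    df = df.copy()
    df.columns = new
    return df.loc[:, ~df.columns.duplicated()]


def align_cohort(
    expression: GeneExpressionMatrix,
    clinical: ClinicalTable,
    cn: Optional[CopyNumberMatrix] = None,
    mutations: Optional[MutationMatrix] = None,
    mirna: Optional[MiRNAMatrix] = None,
    name: str = "cohort",
    id_prefix_len: Optional[int] = None,
) -> tuple[CohortBundle, dict[str, int]]:
    """Align omics layers on the clinical table's sample IDs.

    Each layer is subset to the samples it shares with the clinical table;
    layers covering only a subset of samples are retained with their own
    (smaller) sample list.  Sample IDs can optionally be truncated to a
    fixed prefix length before matching (barcode-style IDs that encode
    aliquot/portion suffixes need truncation to the patient level).

    Returns the bundle and a dict of per-layer sample counts.

    Raises
    ------
    ValueError
        if the expression and clinical sample sets are disjoint.
    """
    clin_df = _dedupe_truncated(clinical.table.T, id_prefix_len).T
    clin_ids = list(clin_df.index)

    expr_df = _dedupe_truncated(expression.values, id_prefix_len)
    expr_keep = [s for s in expr_df.columns if s in set(clin_ids)]
    if not expr_keep:
        raise ValueError("no samples shared between expression and clinical table")
    counts = {"clinical": len(clin_ids), "expression": len(expr_keep)}

    keep_clin = [s for s in clin_ids if s in set(expr_keep)]
    bundle_kwargs: dict = {
        "name": name,
        "expression": GeneExpressionMatrix(expr_df[expr_keep], expression.standardized),
        "clinical": ClinicalTable(clin_df.loc[keep_clin]),
    }

    if cn is not None:
        cn_df = _dedupe_truncated(cn.scores, id_prefix_len)
        keep = [s for s in cn_df.columns if s in set(keep_clin)]
        counts["cn"] = len(keep)
        bundle_kwargs["cn"] = CopyNumberMatrix(cn_df[keep]) if keep else None
    if mutations is not None:
        mut_df = _dedupe_truncated(mutations.mutated, id_prefix_len)
        keep = [s for s in mut_df.columns if s in set(keep_clin)]
        counts["mutations"] = len(keep)
        bundle_kwargs["mutations"] = MutationMatrix(mut_df[keep]) if keep else None
    if mirna is not None:
        mir_df = _dedupe_truncated(mirna.values, id_prefix_len)
        cls = mirna.sample_class.copy()
        cls.index = _truncate_ids(cls.index, id_prefix_len)
        cls = cls[~cls.index.duplicated()]
        tumor_keep = [s for s in mir_df.columns
                      if cls.get(s) == "normal" or s in set(keep_clin)]
        n_tumor = sum(1 for s in tumor_keep if cls.get(s) == "tumor")
        counts["mirna"] = n_tumor
        if n_tumor:
            bundle_kwargs["mirna"] = MiRNAMatrix(mir_df[tumor_keep], cls[tumor_keep])

    return CohortBundle(**bundle_kwargs), counts


def match_signature_genes(
    cohort: CohortBundle, sig: GeneSet, coverage_floor: float = 0.5
) -> tuple[GeneSet, float]:
    """Intersect a signature with the cohort's measured genes.

    Returns the working gene set (signature genes present on this cohort's
    platform, in signature order) and the coverage fraction.  Coverage
    below ``coverage_floor`` raises, since compound-covariate scores built
    on too few genes are not comparable with the trained score model.
    """
    present = set(cohort.expression.gene_ids)
    kept = tuple(g for g in sig.gene_ids if g in present)
    coverage = len(kept) / len(sig.gene_ids)
    if coverage < coverage_floor:
        raise ValueError(
            f"signature coverage {coverage:.2f} below floor {coverage_floor:.2f}; "
            "classification on this platform is not advised"
        )
    return GeneSet(sig.name, kept, sig.description), coverage
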