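"""Readers and writers for the tab-delimited formats the pipeline consumes.

Matrices are genes (or miRNAs) in rows with a header row of sample IDs.
The GISTIC ``all_thresholded.by_genes`` dialect is accepted by dropping its
``Locus ID``/``Cytoband`` annotation columns.  Mutations come from a
MAF-like table (Hugo_Symbol, Tumor_Sample_Barcode, Variant_Classification).
Gene sets use GMT.  Unknown clinical values are encoded ``NA``.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .datamodel import (
    ClinicalTable,
    CopyNumberMatrix,
    GeneExpressionMatrix,
    GeneSet,
    MiRNAMatrix,
    MutationMatrix,
)

PathLike = Union[str, Path]

# MAF variant classes treated as silent (excluded from the binary matrix)
DEFAULT_SILENT_CLASSES = frozenset(
    {"Silent", "Intron", "3'UTR", "5'UTR", "IGR", "RNA"}
)


def _read_matrix(path: PathLike, what: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty matrix in {path}")
    out = pd.DataFrame(index=df.index, columns=df.columns, dtype=float)
    for col in df.columns:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = df.index[bad.argmax()]
            raise ValueError(
                f"non-numeric {what} value at row {row!r}, column {col!r} in {path}"
            )
        out[col] = converted
    if out.isna().any().any():
        row, col = next(zip(*np.where(out.isna().to_numpy())))
        raise ValueError(
            f"missing {what} value at row {out.index[row]!r}, "
            f"column {out.columns[col]!r} in {path}"
        )
    return out


def read_expression(path: PathLike) -> GeneExpressionMatrix:
    """Read a tab-delimited gene x sample log2 expression matrix.

    Gene symbols are uppercased; duplicate gene rows are collapsed by
    averaging.  The result is flagged un-standardized.
    """
    df = _read_matrix(path, "expression")
    df.index = df.index.astype(str).str.upper()
    if df.index.duplicated().any():
        df = df.groupby(level=0, sort=False).mean()
    return GeneExpressionMatrix(df, standardized=False)


def write_expression(m: GeneExpressionMatrix, path: PathLike) -> None:
    m.values.to_csv(path, sep="\t", index_label="gene", float_format="%.17g")


def read_copy_number(path: PathLike) -> CopyNumberMatrix:
    """Read a gene-level thresholded GISTIC table.

    Annotation columns of the ``all_thresholded.by_genes`` dialect
    (``Locus ID``, ``Cytoband``) are ignored when present.
    """
    df = pd.read_csv(path, sep="\t", index_col=0)
    drop = [c for c in df.columns if c.strip().lower() in ("locus id", "cytoband")]
    df = df.drop(columns=drop)
    if df.shape[0] == 0 or df.shape[1] == 0:
        raise ValueError(f"empty copy-number matrix in {path}")
    df.index = df.index.astype(str).str.upper()
    df = df[~df.index.duplicated()]
    return CopyNumberMatrix(df.astype(int))


def write_copy_number(m: CopyNumberMatrix, path: PathLike) -> None:
    m.scores.to_csv(path, sep="\t", index_label="gene")


def read_maf(
    path: PathLike,
    silent_classes: Iterable[str] = DEFAULT_SILENT_CLASSES,
    gene_ids: Optional[Sequence[str]] = None,
    sample_ids: Optional[Sequence[str]] = None,
) -> MutationMatrix:
    """Build a binary mutation matrix from a MAF-like mutation table.

    A gene/sample cell is 1 if the table contains at least one mutation of
    a non-silent class for that pair.  ``gene_ids``/``sample_ids`` extend
    the matrix to a fixed universe (rows/columns without mutations are 0).
    """
    maf = pd.read_csv(path, sep="\t", dtype=str, comment="#")
    required = {"Hugo_Symbol", "Tumor_Sample_Barcode", "Variant_Classification"}
    missing = required - set(maf.columns)
    if missing:
        raise ValueError(f"MAF file missing columns: {sorted(missing)}")
    silent = set(silent_classes)
    maf = maf[~maf["Variant_Classification"].isin(silent)]
    maf["Hugo_Symbol"] = maf["Hugo_Symbol"].str.upper()
    genes = sorted(set(maf["Hugo_Symbol"]) | set(g.upper() for g in gene_ids or ()))
    samples = sorted(set(maf["Tumor_Sample_Barcode"]) | set(sample_ids or ()))
    mat = pd.DataFrame(0, index=genes, columns=samples, dtype=int)
    for gene, sample in zip(maf["Hugo_Symbol"], maf["Tumor_Sample_Barcode"]):
        mat.loc[gene, sample] = 1
    return MutationMatrix(mat)


def write_mutations(m: MutationMatrix, path: PathLike) -> None:
    m.mutated.to_csv(path, sep="\t", index_label="gene")


def read_mirna(path: PathLike, class_path: PathLike) -> MiRNAMatrix:
    """Read a miRNA matrix plus a two-column sample/class table."""
    df = _read_matrix(path, "miRNA")
    cls = pd.read_csv(class_path, sep="\t", index_col=0)["sample_class"]
    return MiRNAMatrix(df, cls)


def write_mirna(m: MiRNAMatrix, path: PathLike, class_path: PathLike) -> None:
    m.values.to_csv(path, sep="\t", index_label="mirna", float_format="%.17g")
    m.sample_class.rename("sample_class").to_csv(
        class_path, sep="\t", index_label="sample_id"
    )


def read_clinical(path: PathLike) -> ClinicalTable:
    df = pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], dtype={0: str})
    return ClinicalTable(df)


def write_clinical(c: ClinicalTable, path: PathLike) -> None:
    c.table.to_csv(path, sep="\t", index_label="sample_id", na_rep="NA")


def read_gmt(path: PathLike) -> list[GeneSet]:
    sets = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise ValueError(f"malformed GMT line: {line[:60]!r}")
            sets.append(GeneSet(parts[0], tuple(parts[2:]), description=parts[1]))
    return sets


def write_gmt(sets: Iterable[GeneSet], path: PathLike) -> None:
    with open(path, "w") as fh:
        for s in sets:
            fh.write("\t".join([s.name, s.description, *s.gene_ids]) + "\n")
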