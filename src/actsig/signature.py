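"""Dual correlation screen for driver-activation signatures.

Downstream targets of an amplified driver are identified by two marginal
Pearson screens over all measured genes: correlation of each gene's
expression with (a) the driver's thresholded copy-number score and (b) the
driver's own mRNA.  Genes passing P < 0.001 and |r| > 0.2 in a screen form
the copy-number-associated and mRNA-associated lists; the activation
signature is their intersection, with the driver itself excluded (it
passes both screens trivially but is not a downstream target).

No multiple-testing correction is applied: the raw P < 0.001 rule is the
screen's definition, kept deliberately.  Pearson r is invariant to
per-gene standardization, so the screen runs on unstandardized log2
expression.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import CohortBundle, GeneSet

__all__ = [
    "CorrelationRecord",
    "SignatureThresholds",
    "SignatureResult",
    "correlate_all_genes",
    "derive_signature",
]


@dataclass(frozen=True)
class SignatureThresholds:
    p_max: float = 0.001
    r_min: float = 0.2  # exclusive: |r| must strictly exceed this


@dataclass
class CorrelationRecord:
    """Per-gene evidence from the two screens."""

    gene_id: str
    r_cn: float
    p_cn: float
    r_mrna: float
    p_mrna: float


@dataclass
class SignatureResult:
    """Outcome of the dual screen.

    ``signature`` is None when the intersection is empty (a warning-level
    outcome, not an error).
    """

    cn_associated: GeneSet | None
    mrna_associated: GeneSet | None
    signature: GeneSet | None
    records: list[CorrelationRecord]
    thresholds: SignatureThresholds

    @property
    def n_cn(self) -> int:
        return len(self.cn_associated) if self.cn_associated else 0

    @property
    def n_mrna(self) -> int:
        return len(self.mrna_associated) if self.mrna_associated else 0

    @property
    def n_signature(self) -> int:
        return len(self.signature) if self.signature else 0

    def records_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(r.gene_id, r.r_cn, r.p_cn, r.r_mrna, r.p_mrna) for r in self.records],
            columns=["gene_id", "r_cn", "p_cn", "r_mrna", "p_mrna"],
        ).set_index("gene_id")


def _pearson_vs_vector(x: np.ndarray, y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Row-wise Pearson r of matrix ``x`` against vector ``y`` with
    two-sided p from the t distribution on n-2 df."""
    n = y.size
    xc = x - x.mean(axis=1, keepdims=True)
    yc = y - y.mean()
    num = xc @ yc
    den = np.sqrt((xc ** 2).sum(axis=1) * (yc ** 2).sum())
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / den, np.nan)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
        t = r * np.sqrt((n - 2) / np.maximum(1.0 - r ** 2, np.finfo(float).tiny))
    p = 2.0 * stats.t.sf(np.abs(t), df=n - 2)
    p = np.where(np.isnan(r), np.nan, p)
    return r, p


def correlate_all_genes(cohort: CohortBundle, driver: str) -> list[CorrelationRecord]:
    """Pearson-correlate every gene's expression with the driver's GISTIC
    score and with the driver's mRNA, across the samples shared by the
    expression and copy-number layers.

    The thresholded GISTIC integers are used directly as the numeric
    copy-number covariate.
    """
    driver = driver.upper()
    if cohort.cn is None:
        raise ValueError("cohort has no copy-number layer")
    if driver not in set(cohort.expression.gene_ids):
        raise ValueError(f"driver {driver!r} absent from expression matrix")
    if driver not in set(cohort.cn.gene_ids):
        raise ValueError(f"driver {driver!r} absent from copy-number matrix")

    shared = [s for s in cohort.expression.sample_ids
              if s in set(cohort.cn.sample_ids)]
    if len(shared) < 4:
        raise ValueError(
            f"only {len(shared)} samples shared between expression and CN; need >=4"
        )
    x = cohort.expression.values[shared].to_numpy(dtype=float)
    gistic = cohort.cn.scores.loc[driver, shared].to_numpy(dtype=float)
    mrna = cohort.expression.values.loc[driver, shared].to_numpy(dtype=float)

    r_cn, p_cn = _pearson_vs_vector(x, gistic)
    r_mrna, p_mrna = _pearson_vs_vector(x, mrna)
    genes = cohort.expression.gene_ids
    return [
        CorrelationRecord(g, float(r_cn[i]), float(p_cn[i]),
                          float(r_mrna[i]), float(p_mrna[i]))
        for i, g in enumerate(genes)
    ]


def derive_signature(
    records: list[CorrelationRecord],
    thresholds: SignatureThresholds = SignatureThresholds(),
    driver: str | None = None,
) -> SignatureResult:
    """Apply the dual thresholds and intersect the two gene lists.

    A gene enters a list when its p-value is below ``p_max`` and |r|
    strictly exceeds ``r_min``.  The driver (if named) is excluded from
    the final signature.  An empty intersection yields an empty result,
    not an error.
    """
    if not records:
        raise ValueError("no correlation records supplied")
    t = thresholds
    cn_genes = tuple(
        r.gene_id for r in records
        if np.isfinite(r.r_cn) and r.p_cn < t.p_max and abs(r.r_cn) > t.r_min
    )
    mrna_genes = tuple(
        r.gene_id for r in records
        if np.isfinite(r.r_mrna) and r.p_mrna < t.p_max and abs(r.r_mrna) > t.r_min
    )
    drv = driver.upper() if driver else None
    sig_genes = tuple(
        g for g in cn_genes if g in set(mrna_genes) and g != drv
    )
    return SignatureResult(
        cn_associated=GeneSet("cn_associated", cn_genes) if cn_genes else None,
        mrna_associated=GeneSet("mrna_associated", mrna_genes) if mrna_genes else None,
        signature=GeneSet("activation_signature", sig_genes) if sig_genes else None,
        records=list(records),
        thresholds=t,
    )
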