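"""Subtype association battery.

Given per-sample activation calls, these screens test which genomic and
clinical features travel with the activated subtype:

* per-gene copy-number Fisher screens — amplification counts high-level
  events only (GISTIC >= 2) while deletion counts all loss events
  (GISTIC <= -1);
* per-gene mutation Fisher screens on a significantly-mutated-gene panel;
* differential miRNA expression (pooled-variance t-test) with the
  fold-change > 2 / P < 0.001 filter, two-sidedly (FC >= 2 or <= 0.5);
* the staged copy-number-independent (CNI) miRNA screen: miRNAs that
  separate CNI-activated from copy-number-driven activated tumors
  (fold ratio > 1.5, P < 0.01), differ from normal tissue (P < 0.05), and
  are higher in CNI-activated tumors than in both inactivated tumors and
  normals;
* cross-tabulations of subtype against categorical labels (HPV status,
  molecular subtype), Fisher for 2 levels, chi-square for K > 2;
* the interferon-gamma composite score (mean of CXCL9, CXCL10, IDO1,
  IFNG, HLA-DRA, STAT1) compared between subtypes and correlated with the
  classifier's posterior probability.

No multiple-testing correction feeds the filters — raw thresholds are the
screens' definitions — but every result table carries a
Benjamini-Hochberg q column for the reader's information.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .bccp import ClassProbability
from .datamodel import CohortBundle, GeneExpressionMatrix
from .simulate import IFNG_GENES

__all__ = [
    "ContingencyResult",
    "DifferentialResult",
    "CNIScreenResult",
    "CrosstabResult",
    "IFNGAssociation",
    "fisher_exact_2x2",
    "compare_cn_events",
    "compare_mutations",
    "differential_mirna",
    "cni_mirna_screen",
    "crosstab_subtype",
    "ifng_score",
    "ifng_association",
    "calls_frame",
]


def calls_frame(calls: Sequence[ClassProbability]) -> pd.DataFrame:
    """Tabulate classifier calls (sample, score, p_active, label)."""
    return pd.DataFrame(
        [(c.sample_id, c.score, c.p_active, c.label) for c in calls],
        columns=["sample_id", "score", "p_active", "label"],
    ).set_index("sample_id")


def _bh_q(p: np.ndarray) -> np.ndarray:
    ok = np.isfinite(p)
    q = np.full_like(p, np.nan, dtype=float)
    if ok.any():
        q[ok] = stats.false_discovery_control(p[ok], method="bh")
    return q


@dataclass
class ContingencyResult:
    feature_id: str
    a: int  # feature present, group A (activated)
    b: int  # feature absent, group A
    c: int  # feature present, group B (inactivated)
    d: int  # feature absent, group B
    odds_ratio: float  # (a*d)/(b*c); NaN when undefined (zero denominator)
    p_value: float
    rate_a: float = float("nan")  # a/(a+b)
    rate_b: float = float("nan")  # c/(c+d)


def fisher_exact_2x2(table: Sequence[Sequence[int]]) -> tuple[float, float]:
    """Two-sided Fisher exact test on a 2x2 table.

    The two-sided p sums hypergeometric probabilities (margins fixed) of
    every table whose point probability does not exceed the observed
    one's (with a small relative tolerance for floating-point ties).  The
    odds ratio is the cross-product ratio ``(a*d)/(b*c)``, NaN when the
    denominator is zero.
    """
    t = np.asarray(table, dtype=float)
    if t.shape != (2, 2):
        raise ValueError("table must be 2x2")
    if (t < 0).any() or not np.allclose(t, np.round(t)):
        raise ValueError("counts must be non-negative integers")
    t = t.astype(int)
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero margin in contingency table")
    (a, b), (c, d) = t
    odds = (a * d) / (b * c) if b * c > 0 else float("nan")
    _, p = stats.fisher_exact(t, alternative="two-sided")
    return float(odds), float(p)


def _subtype_masks(
    calls: Sequence[ClassProbability], sample_ids: Sequence[str]
) -> tuple[list[str], list[str]]:
    lab = calls_frame(calls)["label"]
    present = [s for s in sample_ids if s in lab.index]
    ya = [s for s in present if lab[s] == "YA"]
    yi = [s for s in present if lab[s] == "YI"]
    return ya, yi


def _event_screen(
    mat: pd.DataFrame, ya: list[str], yi: list[str], event: pd.DataFrame,
    suffix: str,
) -> list[ContingencyResult]:
    results = []
    ev_ya = event[ya].to_numpy()
    ev_yi = event[yi].to_numpy()
    for i, gene in enumerate(mat.index):
        a = int(ev_ya[i].sum()); b = len(ya) - a
        c = int(ev_yi[i].sum()); d = len(yi) - c
        if a + c == 0:
            odds, p = float("nan"), 1.0
        else:
            odds, p = fisher_exact_2x2([[a, b], [c, d]])
        results.append(ContingencyResult(
            f"{gene}{suffix}", a, b, c, d, odds, p,
            rate_a=a / len(ya), rate_b=c / len(yi),
        ))
    return results


def contingency_frame(results: Sequence[ContingencyResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(r.feature_id, r.a, r.b, r.c, r.d, r.odds_ratio, r.p_value,
          r.rate_a, r.rate_b) for r in results],
        columns=["feature_id", "a", "b", "c", "d", "odds_ratio", "p_value",
                 "rate_activated", "rate_inactivated"],
    ).set_index("feature_id")
    df["q_value"] = _bh_q(df["p_value"].to_numpy())
    return df


def compare_cn_events(
    cohort: CohortBundle, calls: Sequence[ClassProbability]
) -> list[ContingencyResult]:
    """Per-gene Fisher screens of copy-number events by subtype.

    Each gene is tested twice: amplification (GISTIC >= 2, high-level
    events only) and deletion (GISTIC <= -1, all loss events), each
    cross-tabulated activated/inactivated x event/no-event.
    """
    if cohort.cn is None:
        raise ValueError("cohort has no copy-number layer")
    ya, yi = _subtype_masks(calls, cohort.cn.sample_ids)
    if not ya or not yi:
        raise ValueError("no overlapping samples in one of the subtypes")
    scores = cohort.cn.scores
    out = _event_screen(scores, ya, yi, scores >= 2, ":amp")
    out += _event_screen(scores, ya, yi, scores <= -1, ":del")
    return out


def compare_mutations(
    cohort: CohortBundle,
    calls: Sequence[ClassProbability],
    gene_panel: Sequence[str],
) -> list[ContingencyResult]:
    """Per-gene mutated/wild-type Fisher tests by subtype, with per-group
    mutation rates.  Panel genes absent from the matrix are skipped with
    a warning."""
    import warnings

    if cohort.mutations is None:
        raise ValueError("cohort has no mutation layer")
    mut = cohort.mutations.mutated
    ya, yi = _subtype_masks(calls, cohort.mutations.sample_ids)
    if not ya or not yi:
        raise ValueError("no overlapping samples in one of the subtypes")
    results = []
    for gene in gene_panel:
        gene = gene.upper()
        if gene not in mut.index:
            warnings.warn(f"gene {gene} absent from mutation matrix; skipped")
            continue
        a = int(mut.loc[gene, ya].sum()); b = len(ya) - a
        c = int(mut.loc[gene, yi].sum()); d = len(yi) - c
        if a + c == 0:
            odds, p = float("nan"), 1.0
        else:
            odds, p = fisher_exact_2x2([[a, b], [c, d]])
        results.append(ContingencyResult(
            gene, a, b, c, d, odds, p, rate_a=a / len(ya), rate_b=c / len(yi),
        ))
    return results


@dataclass
class DifferentialResult:
    feature_id: str
    mean_a: float           # log2 means
    mean_b: float
    fold_change: float      # 2 ** (mean_a - mean_b)
    t_statistic: float
    p_value: float
    passes: bool


def _pooled_t(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
    t, p = stats.ttest_ind(x, y, equal_var=True)
    return float(t), float(p)


def differential_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        [(r.feature_id, r.mean_a, r.mean_b, r.fold_change, r.t_statistic,
          r.p_value, r.passes) for r in results],
        columns=["feature_id", "mean_activated", "mean_inactivated",
                 "fold_change", "t_statistic", "p_value", "passes"],
    ).set_index("feature_id")
    df["q_value"] = _bh_q(df["p_value"].to_numpy())
    return df


def differential_mirna(
    cohort: CohortBundle,
    calls: Sequence[ClassProbability],
    p_max: float = 0.001,
    fc_min: float = 2.0,
    equal_var: bool = True,
) -> list[DifferentialResult]:
    """Activated-vs-inactivated differential miRNA expression.

    Pooled-variance two-sample t-test on log2 values (Welch via
    ``equal_var=False``); a miRNA passes when p < ``p_max`` and the fold
    change is at least ``fc_min`` in either direction (FC >= 2 or
    FC <= 0.5 at the default).
    """
    if cohort.mirna is None:
        raise ValueError("cohort has no miRNA layer")
    ya, yi = _subtype_masks(calls, cohort.mirna.tumor_ids)
    if len(ya) < 3 or len(yi) < 3:
        raise ValueError("fewer than 3 samples in a subtype")
    vals = cohort.mirna.values
    results = []
    for mid in cohort.mirna.mirna_ids:
        x = vals.loc[mid, ya].to_numpy(float)
        y = vals.loc[mid, yi].to_numpy(float)
        t, p = stats.ttest_ind(x, y, equal_var=equal_var)
        fc = 2.0 ** (x.mean() - y.mean())
        passes = bool(p < p_max and (fc >= fc_min or fc <= 1.0 / fc_min))
        results.append(DifferentialResult(
            mid, float(x.mean()), float(y.mean()), float(fc), float(t),
            float(p), passes,
        ))
    return results


@dataclass
class CNIScreenResult:
    """Staged screen for miRNAs specific to copy-number-independent
    activation; the three lists are nested (final within stage 2 within
    stage 1)."""

    stage1: list[str]   # CNI-YA vs CND-YA, |fold ratio| > 1.5 & p < 0.01
    stage2: list[str]   # stage1 members also different from normals, p < 0.05
    final: list[str]    # stage2 members higher in CNI-YA than YI and normals
    table: pd.DataFrame


def cni_mirna_screen(
    cohort: CohortBundle,
    calls: Sequence[ClassProbability],
    driver: str,
    fold_ratio_min: float = 1.5,
    p_stage1: float = 0.01,
    p_stage2: float = 0.05,
    equal_var: bool = True,
) -> CNIScreenResult:
    """Find miRNAs elevated specifically in copy-number-independent
    activated tumors (a candidate miRNA-mediated activation mechanism).

    Activated tumors are partitioned by the driver's GISTIC score into
    copy-number-dependent (>= 2) and copy-number-independent (< 2).
    Stage 1 keeps miRNAs separating CNI from CND activation (fold ratio >
    1.5 either way, p < 0.01); stage 2 keeps those also differing from
    normal tissue (p < 0.05); the final list keeps those whose CNI mean
    exceeds both the inactivated-tumor mean and the normal mean.
    """
    driver = driver.upper()
    if cohort.mirna is None:
        raise ValueError("cohort has no miRNA layer")
    if cohort.cn is None:
        raise ValueError("cohort has no copy-number layer")
    normals = cohort.mirna.normal_ids
    if not normals:
        raise ValueError("no normal samples in the miRNA layer")
    lab = calls_frame(calls)["label"]
    gistic = cohort.cn.scores.loc[driver]
    tumor_ids = [s for s in cohort.mirna.tumor_ids
                 if s in lab.index and s in gistic.index]
    ya = [s for s in tumor_ids if lab[s] == "YA"]
    yi = [s for s in tumor_ids if lab[s] == "YI"]
    cnd = [s for s in ya if gistic[s] >= 2]
    cni = [s for s in ya if gistic[s] < 2]
    if not cni:
        raise ValueError("no copy-number-independent activated tumors")
    if not cnd:
        raise ValueError("no copy-number-dependent activated tumors")

    vals = cohort.mirna.values
    rows = []
    for mid in cohort.mirna.mirna_ids:
        x_cni = vals.loc[mid, cni].to_numpy(float)
        x_cnd = vals.loc[mid, cnd].to_numpy(float)
        x_yi = vals.loc[mid, yi].to_numpy(float)
        x_nrm = vals.loc[mid, normals].to_numpy(float)
        t1, p1 = stats.ttest_ind(x_cni, x_cnd, equal_var=equal_var)
        fr = 2.0 ** (x_cni.mean() - x_cnd.mean())
        in1 = bool(p1 < p_stage1 and (fr >= fold_ratio_min or fr <= 1 / fold_ratio_min))
        t2, p2 = stats.ttest_ind(x_cni, x_nrm, equal_var=equal_var)
        in2 = bool(in1 and p2 < p_stage2)
        in_final = bool(
            in2 and x_cni.mean() > x_yi.mean() and x_cni.mean() > x_nrm.mean()
        )
        rows.append((mid, x_cni.mean(), x_cnd.mean(), x_yi.mean(), x_nrm.mean(),
                     fr, p1, p2, in1, in2, in_final))
    table = pd.DataFrame(rows, columns=[
        "mirna_id", "mean_cni", "mean_cnd", "mean_inactive", "mean_normal",
        "fold_ratio", "p_cni_vs_cnd", "p_cni_vs_normal",
        "stage1", "stage2", "final",
    ]).set_index("mirna_id")
    return CNIScreenResult(
        stage1=list(table.index[table["stage1"]]),
        stage2=list(table.index[table["stage2"]]),
        final=list(table.index[table["final"]]),
        table=table,
    )


@dataclass
class CrosstabResult:
    counts: pd.DataFrame    # levels x subtype counts
    percents: pd.DataFrame  # column percentages
    p_value: float
    method: str             # "fisher" / "chi2"


def crosstab_subtype(
    calls: Sequence[ClassProbability], labels: pd.Series
) -> CrosstabResult:
    """Cross-tabulate subtype calls against a categorical label.

    Two-level labels use the Fisher exact test; labels with more levels
    use the chi-square test of independence.
    """
    lab = calls_frame(calls)["label"]
    shared = [s for s in lab.index if s in labels.index and pd.notna(labels[s])]
    sub = pd.DataFrame({"subtype": lab[shared], "label": labels[shared]})
    if sub["label"].nunique() < 2:
        raise ValueError("label has fewer than 2 observed levels")
    if sub["subtype"].nunique() < 2:
        raise ValueError("all samples fall in one subtype")
    counts = pd.crosstab(sub["label"], sub["subtype"])
    if counts.shape[0] == 2:
        _, p = fisher_exact_2x2(counts.to_numpy())
        method = "fisher"
    else:
        _, p, _, _ = stats.chi2_contingency(counts.to_numpy())
        method = "chi2"
    percents = counts / counts.sum(axis=0) * 100.0
    return CrosstabResult(counts, percents, float(p), method)


def ifng_score(
    expr: GeneExpressionMatrix,
    genes: Sequence[str] = IFNG_GENES,
    min_present: int = 5,
) -> pd.Series:
    """Interferon-gamma composite score: per-sample mean of the six
    response genes on per-cohort standardized expression.

    Computed when at least ``min_present`` of the genes are measured;
    otherwise raises, listing the missing genes.
    """
    genes = [g.upper() for g in genes]
    present = [g for g in genes if g in set(expr.gene_ids)]
    if len(present) < min_present:
        missing = [g for g in genes if g not in set(expr.gene_ids)]
        raise ValueError(
            f"only {len(present)} of {len(genes)} interferon-gamma genes "
            f"present (need >= {min_present}); missing: {missing}"
        )
    return expr.values.loc[present].mean(axis=0).rename("ifng_score")


@dataclass
class IFNGAssociation:
    mean_activated: float
    mean_inactivated: float
    t_statistic: float
    t_p_value: float
    pearson_r: float        # score vs posterior probability of activation
    pearson_p: float


def ifng_association(
    scores: pd.Series, calls: Sequence[ClassProbability], equal_var: bool = True
) -> IFNGAssociation:
    """Compare composite scores between subtypes (t-test) and correlate
    them with the classifier's posterior activation probability."""
    cf = calls_frame(calls)
    shared = [s for s in cf.index if s in scores.index]
    ya = [s for s in shared if cf.loc[s, "label"] == "YA"]
    yi = [s for s in shared if cf.loc[s, "label"] == "YI"]
    if len(ya) < 2 or len(yi) < 2:
        raise ValueError("need at least 2 samples per subtype")
    x, y = scores[ya].to_numpy(float), scores[yi].to_numpy(float)
    t, p = stats.ttest_ind(x, y, equal_var=equal_var)
    r, rp = stats.pearsonr(scores[shared], cf.loc[shared, "p_active"])
    return IFNGAssociation(
        float(x.mean()), float(y.mean()), float(t), float(p), float(r), float(rp)
    )
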