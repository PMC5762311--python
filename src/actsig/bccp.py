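"""Bayesian compound covariate predictor (BCCP).

The classifier combines a gene signature into a single compound covariate
per sample, ``s_j = sum_g w_g x_gj``, where the weight ``w_g`` is the
pooled-variance two-sample t-statistic of gene ``g`` between the active
and inactive training classes (active minus inactive).  Training classes
come from the driver's thresholded copy number: active iff GISTIC >= 2
(high-level amplification).

Scores in each training class are modelled as Gaussians with class means
``mu_A``, ``mu_I`` and a shared pooled SD ``sigma``; with priors
``pi_A = pi_I = 0.5`` the posterior probability of activation given a
score ``s`` is

    p_A(s) = pi_A phi(s; mu_A, sigma) /
             [pi_A phi(s; mu_A, sigma) + pi_I phi(s; mu_I, sigma)]

A sample is called activated (YA) iff ``p_A > 0.5``; a posterior of
exactly 0.5 is labelled inactivated, since activation is defined strictly
as "> 0.5".

Expression must be standardized per cohort (mean 0, SD 1 per gene) before
fitting or prediction; the compound score is otherwise platform-dependent.
When a test platform measures only a subset of the model's genes, the
stored training expression is re-scored under the reduced gene set and the
Gaussians refit, because compound scores scale with gene count.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .datamodel import CohortBundle, GeneExpressionMatrix, GeneSet

__all__ = [
    "TrainingClasses",
    "BCCPModel",
    "ClassProbability",
    "make_training_classes",
    "fit_bccp",
    "predict_bccp",
    "loocv_misclassification",
    "assign_subtypes",
    "multiclass_bccp",
    "write_model",
    "read_model",
]

MIN_CLASS_SIZE = 3  # t-statistics are unstable below this


@dataclass
class TrainingClasses:
    """Sample -> active/inactive labels derived from driver copy number."""

    labels: pd.Series  # values "active" / "inactive"

    def __post_init__(self) -> None:
        bad = set(self.labels.unique()) - {"active", "inactive"}
        if bad:
            raise ValueError(f"unexpected class labels: {bad}")

    @property
    def active_ids(self) -> list[str]:
        return list(self.labels[self.labels == "active"].index)

    @property
    def inactive_ids(self) -> list[str]:
        return list(self.labels[self.labels == "inactive"].index)


@dataclass
class ClassProbability:
    sample_id: str
    score: float
    p_active: float
    label: str  # "YA" / "YI"


@dataclass
class BCCPModel:
    """Fitted compound covariate classifier.

    ``training_expression`` retains the standardized training matrix
    restricted to the signature genes, so score Gaussians can be refit
    when a test platform covers only part of the gene list.
    """

    gene_ids: tuple[str, ...]
    weights: np.ndarray
    mu_active: float
    mu_inactive: float
    sigma: float
    prior_active: float = 0.5
    training_cohort: str = ""
    n_active: int = 0
    n_inactive: int = 0
    gistic_threshold: int = 2
    training_expression: Optional[pd.DataFrame] = None
    training_labels: Optional[pd.Series] = None

    def __post_init__(self) -> None:
        if len(self.gene_ids) != len(self.weights):
            raise ValueError("gene_ids and weights length mismatch")
        if self.sigma <= 0:
            raise ValueError("sigma must be positive")
        if not 0 < self.prior_active < 1:
            raise ValueError("prior_active must lie in (0, 1)")

    @property
    def prior_inactive(self) -> float:
        return 1.0 - self.prior_active


def make_training_classes(
    cohort: CohortBundle, driver: str, threshold: int = 2
) -> TrainingClasses:
    """Active iff the driver's GISTIC score >= ``threshold`` (high-level
    amplification), inactive otherwise; restricted to samples with both
    expression and copy-number data."""
    driver = driver.upper()
    if cohort.cn is None:
        raise ValueError("cohort has no copy-number layer")
    if driver not in set(cohort.cn.gene_ids):
        raise ValueError(f"driver {driver!r} absent from copy-number matrix")
    shared = [s for s in cohort.expression.sample_ids
              if s in set(cohort.cn.sample_ids)]
    scores = cohort.cn.scores.loc[driver, shared]
    labels = pd.Series(
        np.where(scores >= threshold, "active", "inactive"), index=shared
    )
    n_a = int((labels == "active").sum())
    n_i = int((labels == "inactive").sum())
    if n_a < MIN_CLASS_SIZE:
        what = "active class empty" if n_a == 0 else f"active class has {n_a} samples"
        raise ValueError(f"{what} (need >= {MIN_CLASS_SIZE})")
    if n_i < MIN_CLASS_SIZE:
        what = "inactive class empty" if n_i == 0 else f"inactive class has {n_i} samples"
        raise ValueError(f"{what} (need >= {MIN_CLASS_SIZE})")
    return TrainingClasses(labels)


def _t_statistics(x_a: np.ndarray, x_i: np.ndarray) -> np.ndarray:
    """Row-wise pooled-variance two-sample t (active minus inactive)."""
    n_a, n_i = x_a.shape[1], x_i.shape[1]
    mean_a = x_a.mean(axis=1)
    mean_i = x_i.mean(axis=1)
    ss_a = ((x_a - mean_a[:, None]) ** 2).sum(axis=1)
    ss_i = ((x_i - mean_i[:, None]) ** 2).sum(axis=1)
    sp2 = (ss_a + ss_i) / (n_a + n_i - 2)
    se = np.sqrt(sp2 * (1.0 / n_a + 1.0 / n_i))
    with np.errstate(divide="ignore", invalid="ignore"):
        t = np.where(se > 0, (mean_a - mean_i) / se, 0.0)
    return t


def _score_gaussians(
    scores: pd.Series, labels: pd.Series
) -> tuple[float, float, float]:
    s_a = scores[labels == "active"].to_numpy()
    s_i = scores[labels == "inactive"].to_numpy()
    mu_a, mu_i = float(s_a.mean()), float(s_i.mean())
    n = s_a.size + s_i.size
    pooled = (((s_a - mu_a) ** 2).sum() + ((s_i - mu_i) ** 2).sum()) / (n - 2)
    sigma = math.sqrt(pooled)
    if sigma <= 0:
        raise ValueError("zero pooled score variance; classes are degenerate")
    return mu_a, mu_i, sigma


def fit_bccp(
    expr: GeneExpressionMatrix,
    classes: TrainingClasses,
    sig: GeneSet,
    prior_active: float = 0.5,
    gistic_threshold: int = 2,
    training_cohort: str = "",
) -> BCCPModel:
    """Fit weights and the class-conditional score Gaussians.

    ``expr`` must be standardized within its cohort and contain every
    signature gene (run :func:`~actsig.datamodel.match_signature_genes`
    first to restrict the signature to the platform).
    """
    if not expr.standardized:
        raise ValueError("expression must be standardized before fitting")
    missing = [g for g in sig.gene_ids if g not in set(expr.gene_ids)]
    if missing:
        raise ValueError(f"signature genes absent from expression: {missing[:5]}")
    ids_a, ids_i = classes.active_ids, classes.inactive_ids
    if min(len(ids_a), len(ids_i)) < MIN_CLASS_SIZE:
        raise ValueError("each training class needs >= 3 samples")
    sub = expr.values.loc[list(sig.gene_ids)]
    w = _t_statistics(sub[ids_a].to_numpy(float), sub[ids_i].to_numpy(float))
    train_ids = ids_a + ids_i
    scores = pd.Series(w @ sub[train_ids].to_numpy(float), index=train_ids)
    mu_a, mu_i, sigma = _score_gaussians(scores, classes.labels[train_ids])
    return BCCPModel(
        gene_ids=tuple(sig.gene_ids), weights=w,
        mu_active=mu_a, mu_inactive=mu_i, sigma=sigma,
        prior_active=prior_active, training_cohort=training_cohort,
        n_active=len(ids_a), n_inactive=len(ids_i),
        gistic_threshold=gistic_threshold,
        training_expression=sub[train_ids].copy(),
        training_labels=classes.labels[train_ids].copy(),
    )


def posterior_active(
    s: np.ndarray | float,
    mu_a: float,
    mu_i: float,
    sigma: float,
    prior_active: float = 0.5,
) -> np.ndarray | float:
    """Gaussian posterior P(active | score), computed in log space."""
    s = np.asarray(s, dtype=float)
    log_a = -0.5 * ((s - mu_a) / sigma) ** 2 + np.log(prior_active)
    log_i = -0.5 * ((s - mu_i) / sigma) ** 2 + np.log(1.0 - prior_active)
    # p_A = 1 / (1 + exp(log_i - log_a))
    p = 1.0 / (1.0 + np.exp(np.clip(log_i - log_a, -700.0, 700.0)))
    return p if p.ndim else float(p)


def _reduced_parameters(
    model: BCCPModel, keep: Sequence[str]
) -> tuple[np.ndarray, float, float, float]:
    """Refit the score Gaussians under a reduced gene set.

    Weights for the remaining genes are unchanged; the stored training
    expression is re-scored with the reduced weight vector, and mu/sigma
    recomputed, since compound scores scale with the number of genes.
    """
    if model.training_expression is None or model.training_labels is None:
        raise ValueError(
            "model lacks stored training expression; cannot refit for a "
            "reduced gene set"
        )
    idx = [model.gene_ids.index(g) for g in keep]
    w = model.weights[idx]
    sub = model.training_expression.loc[list(keep)]
    scores = pd.Series(w @ sub.to_numpy(float), index=sub.columns)
    mu_a, mu_i, sigma = _score_gaussians(scores, model.training_labels)
    return w, mu_a, mu_i, sigma


def predict_bccp(
    model: BCCPModel,
    expr: GeneExpressionMatrix,
    coverage_floor: float = 0.5,
) -> list[ClassProbability]:
    """Score and classify every sample of a (standardized) cohort.

    A sample is YA iff its posterior strictly exceeds 0.5.
    """
    if not expr.standardized:
        raise ValueError("expression must be standardized before prediction")
    present = set(expr.gene_ids)
    keep = [g for g in model.gene_ids if g in present]
    coverage = len(keep) / len(model.gene_ids)
    if coverage < coverage_floor:
        raise ValueError(
            f"model gene coverage {coverage:.2f} below floor {coverage_floor:.2f}"
        )
    if len(keep) < len(model.gene_ids):
        w, mu_a, mu_i, sigma = _reduced_parameters(model, keep)
    else:
        w, mu_a, mu_i, sigma = (model.weights, model.mu_active,
                                model.mu_inactive, model.sigma)
    x = expr.values.loc[keep].to_numpy(float)
    scores = w @ x
    p = posterior_active(scores, mu_a, mu_i, sigma, model.prior_active)
    return [
        ClassProbability(sid, float(s), float(pa), "YA" if pa > 0.5 else "YI")
        for sid, s, pa in zip(expr.sample_ids, scores, np.atleast_1d(p))
    ]


def loocv_misclassification(
    expr: GeneExpressionMatrix,
    classes: TrainingClasses,
    sig: GeneSet,
    prior_active: float = 0.5,
) -> tuple[float, int]:
    """Leave-one-out misclassification rate on the training cohort.

    Each fold refits the gene weights and score Gaussians on the
    remaining n-1 samples (the gene list itself stays fixed — it was
    derived once on the full cohort) and predicts the held-out sample
    against its copy-number-derived class.  Folds that would empty a
    class are skipped with a warning.  Returns (rate, n_evaluated).
    """
    if not expr.standardized:
        raise ValueError("expression must be standardized")
    sub = expr.values.loc[list(sig.gene_ids)]
    train_ids = classes.active_ids + classes.inactive_ids
    labels = classes.labels[train_ids]
    errors = 0
    evaluated = 0
    for held in train_ids:
        rest = [s for s in train_ids if s != held]
        rest_labels = labels[rest]
        n_a = int((rest_labels == "active").sum())
        n_i = int((rest_labels == "inactive").sum())
        if n_a == 0 or n_i == 0:
            warnings.warn(f"LOOCV fold for {held} skipped: a class is empty")
            continue
        ids_a = list(rest_labels[rest_labels == "active"].index)
        ids_i = list(rest_labels[rest_labels == "inactive"].index)
        w = _t_statistics(sub[ids_a].to_numpy(float), sub[ids_i].to_numpy(float))
        scores = pd.Series(w @ sub[rest].to_numpy(float), index=rest)
        mu_a, mu_i, sigma = _score_gaussians(scores, rest_labels)
        s_held = float(w @ sub[held].to_numpy(float))
        p = posterior_active(s_held, mu_a, mu_i, sigma, prior_active)
        call = "active" if p > 0.5 else "inactive"
        evaluated += 1
        if call != labels[held]:
            errors += 1
    if evaluated == 0:
        raise ValueError("no LOOCV folds could be evaluated")
    return errors / evaluated, evaluated


@dataclass
class SubtypeSummary:
    n: int
    n_active: int

    @property
    def fraction_active(self) -> float:
        return self.n_active / self.n if self.n else float("nan")


def assign_subtypes(
    cohort: CohortBundle,
    model: BCCPModel,
    coverage_floor: float = 0.5,
) -> tuple[list[ClassProbability], SubtypeSummary]:
    """Classify a cohort and summarize the activated fraction."""
    calls = predict_bccp(model, cohort.expression, coverage_floor)
    n_active = sum(1 for c in calls if c.label == "YA")
    return calls, SubtypeSummary(n=len(calls), n_active=n_active)


def multiclass_bccp(
    expr: GeneExpressionMatrix,
    class_labels: pd.Series,
    genes: GeneSet,
) -> pd.DataFrame:
    """One-vs-rest BCCP over K classes.

    Each class gets its own compound covariate axis (weights =
    class-vs-rest t-statistics) with Gaussians for "in class" vs "rest";
    per-class posteriors are computed independently on their own axes and
    the label is the argmax.  Ties go to the earliest class in the order
    of first appearance in ``class_labels``.

    Returns a frame indexed by sample with one posterior column per class
    plus a ``label`` column.
    """
    if not expr.standardized:
        raise ValueError("expression must be standardized")
    class_order = list(dict.fromkeys(class_labels))
    if len(class_order) < 2:
        raise ValueError("need at least 2 classes")
    counts = class_labels.value_counts()
    small = [c for c in class_order if counts[c] < MIN_CLASS_SIZE]
    if small:
        raise ValueError(f"classes with < {MIN_CLASS_SIZE} samples: {small}")
    missing = [g for g in genes.gene_ids if g not in set(expr.gene_ids)]
    if missing:
        raise ValueError(f"genes absent from expression: {missing[:5]}")

    sub = expr.values.loc[list(genes.gene_ids)]
    train_ids = list(class_labels.index)
    post = pd.DataFrame(index=expr.sample_ids, columns=class_order, dtype=float)
    for cls in class_order:
        in_ids = list(class_labels[class_labels == cls].index)
        out_ids = [s for s in train_ids if class_labels[s] != cls]
        w = _t_statistics(sub[in_ids].to_numpy(float), sub[out_ids].to_numpy(float))
        scores = pd.Series(w @ sub[train_ids].to_numpy(float), index=train_ids)
        lab = pd.Series(
            np.where(class_labels[train_ids] == cls, "active", "inactive"),
            index=train_ids,
        )
        mu_a, mu_i, sigma = _score_gaussians(scores, lab)
        all_scores = w @ expr.values.loc[list(genes.gene_ids)].to_numpy(float)
        post[cls] = posterior_active(all_scores, mu_a, mu_i, sigma)
    # argmax with ties to the earliest declared class
    arr = post.to_numpy(float)
    best = arr.argmax(axis=1)  # argmax returns the first maximal index
    post["label"] = [class_order[i] for i in best]
    return post


def write_model(model: BCCPModel, path: str | Path) -> None:
    """Serialize to a structured text file (parameter block + gene/weight
    lines).  The stored training expression travels in a sidecar block so
    reduced-gene refits survive a round trip."""
    with open(path, "w") as fh:
        fh.write("#BCCP model\n")
        fh.write(f"mu_active\t{float(model.mu_active)!r}\n")
        fh.write(f"mu_inactive\t{float(model.mu_inactive)!r}\n")
        fh.write(f"sigma\t{float(model.sigma)!r}\n")
        fh.write(f"prior_active\t{float(model.prior_active)!r}\n")
        fh.write(f"training_cohort\t{model.training_cohort}\n")
        fh.write(f"n_active\t{model.n_active}\n")
        fh.write(f"n_inactive\t{model.n_inactive}\n")
        fh.write(f"gistic_threshold\t{model.gistic_threshold}\n")
        fh.write("#weights\n")
        for g, w in zip(model.gene_ids, model.weights):
            fh.write(f"{g}\t{float(w)!r}\n")
        if model.training_expression is not None:
            fh.write("#training_labels\n")
            for sid, lab in model.training_labels.items():
                fh.write(f"{sid}\t{lab}\n")
            fh.write("#training_expression\n")
            fh.write("\t".join(["gene", *model.training_expression.columns]) + "\n")
            for g, row in model.training_expression.iterrows():
                fh.write(g + "\t" + "\t".join(repr(float(v)) for v in row) + "\n")


def read_model(path: str | Path) -> BCCPModel:
    params: dict[str, str] = {}
    genes: list[str] = []
    weights: list[float] = []
    labels: dict[str, str] = {}
    expr_header: list[str] = []
    expr_rows: list[tuple[str, list[float]]] = []
    section = "params"
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line:
                continue
            if line == "#BCCP model":
                continue
            if line == "#weights":
                section = "weights"
                continue
            if line == "#training_labels":
                section = "labels"
                continue
            if line == "#training_expression":
                section = "expr_header"
                continue
            parts = line.split("\t")
            if section == "params":
                params[parts[0]] = parts[1]
            elif section == "weights":
                genes.append(parts[0])
                weights.append(float(parts[1]))
            elif section == "labels":
                labels[parts[0]] = parts[1]
            elif section == "expr_header":
                expr_header = parts[1:]
                section = "expr"
            else:
                expr_rows.append((parts[0], [float(v) for v in parts[1:]]))
    training_expression = None
    training_labels = None
    if expr_rows:
        training_expression = pd.DataFrame(
            [vals for _, vals in expr_rows],
            index=[g for g, _ in expr_rows],
            columns=expr_header,
        )
        training_labels = pd.Series(labels).reindex(expr_header)
    return BCCPModel(
        gene_ids=tuple(genes),
        weights=np.array(weights),
        mu_active=float(params["mu_active"]),
        mu_inactive=float(params["mu_inactive"]),
        sigma=float(params["sigma"]),
        prior_active=float(params["prior_active"]),
        training_cohort=params.get("training_cohort", ""),
        n_active=int(params.get("n_active", 0)),
        n_inactive=int(params.get("n_inactive", 0)),
        gistic_threshold=int(params.get("gistic_threshold", 2)),
        training_expression=training_expression,
        training_labels=training_labels,
    )
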