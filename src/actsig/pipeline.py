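"""End-to-end orchestration: train on one cohort, classify all, run the
downstream battery.  The CLI and example scripts are thin layers over
:func:`run_full`."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Optional, Sequence

import pandas as pd

from . import associations, bccp, signature, survival
from .datamodel import CohortBundle, match_signature_genes, standardize_genes
from .simulate import GroundTruth

log = logging.getLogger(__name__)


@dataclass
class FullRunResult:
    signature_result: signature.SignatureResult
    model: bccp.BCCPModel
    calls: dict[str, list[bccp.ClassProbability]]
    summaries: dict[str, bccp.SubtypeSummary]
    loocv_rate: float
    survival_table: pd.DataFrame
    logrank: tuple[float, float]
    cox_results: list[survival.CoxResult]
    cn_screen: Optional[list[associations.ContingencyResult]]
    mutation_screen: Optional[list[associations.ContingencyResult]]
    mirna_screen: Optional[list[associations.DifferentialResult]]
    cni_screen: Optional[associations.CNIScreenResult]
    hpv_crosstab: Optional[associations.CrosstabResult]
    ifng: Optional[associations.IFNGAssociation]


def pooled_survival_frame(
    cohorts: Sequence[CohortBundle],
    calls: dict[str, list[bccp.ClassProbability]],
    endpoint: str = "os",
) -> pd.DataFrame:
    """Join clinical endpoints with subtype calls across cohorts.

    Covariates are coded as binary indicators: male sex, age >= 60,
    oropharynx site, T4 tumor, node-positive, stage III/IV, activated
    subtype, radiation given.
    """
    frames = []
    for cohort in cohorts:
        cf = associations.calls_frame(calls[cohort.name])
        clin = cohort.clinical.table
        shared = [s for s in cf.index if s in clin.index]
        t = clin.loc[shared]
        frames.append(pd.DataFrame({
            "time": pd.to_numeric(t[f"{endpoint}_time"], errors="coerce"),
            "event": pd.to_numeric(t[f"{endpoint}_event"], errors="coerce"),
            "activated": (cf.loc[shared, "label"] == "YA").astype(int),
            "male": (t["sex"] == "male").astype(int),
            "age_ge_60": (pd.to_numeric(t["age"], errors="coerce") >= 60).astype(int),
            "oropharynx": (t["anatomic_site"] == "oropharynx").astype(int),
            "t4": (t["t_stage"] == "T4").astype(int),
            "node_positive": t["n_stage"].isin(["N1", "N2", "N3"]).astype(int),
            "stage_34": t["overall_stage"].isin(["III", "IV"]).astype(int),
            "radiation": t["radiation"],
            "group": cf.loc[shared, "label"],
            "cohort": cohort.name,
        }, index=shared))
    out = pd.concat(frames)
    return out.dropna(subset=["time", "event"])


def run_full(
    cohorts: Sequence[CohortBundle],
    driver: str,
    thresholds: signature.SignatureThresholds = signature.SignatureThresholds(),
    gistic_threshold: int = 2,
    coverage_floor: float = 0.5,
    five_year: bool = True,
    mutation_panel: Optional[Sequence[str]] = None,
    run_loocv: bool = True,
) -> FullRunResult:
    """Train on the first cohort and apply the whole battery.

    The training cohort must carry a copy-number layer.  The association
    screens run on the training cohort's layers when present; survival
    pools every cohort with the activated-subtype indicator, stratified
    by cohort.
    """
    train = cohorts[0]
    records = signature.correlate_all_genes(train, driver)
    sig_result = signature.derive_signature(records, thresholds, driver=driver)
    if sig_result.signature is None:
        raise ValueError("empty activation signature; screens found no genes")
    log.info("signature: %d genes (cn %d, mrna %d)",
             sig_result.n_signature, sig_result.n_cn, sig_result.n_mrna)

    classes = bccp.make_training_classes(train, driver, gistic_threshold)
    train_std = standardize_genes(train.expression)
    working_sig, coverage = match_signature_genes(
        train, sig_result.signature, coverage_floor)
    model = bccp.fit_bccp(train_std, classes, working_sig,
                          gistic_threshold=gistic_threshold,
                          training_cohort=train.name)
    loocv_rate = float("nan")
    if run_loocv:
        loocv_rate, _ = bccp.loocv_misclassification(train_std, classes, working_sig)

    calls: dict[str, list[bccp.ClassProbability]] = {}
    summaries: dict[str, bccp.SubtypeSummary] = {}
    for cohort in cohorts:
        std = standardize_genes(cohort.expression)
        std_cohort = CohortBundle(
            name=cohort.name, expression=std, clinical=cohort.clinical,
            cn=cohort.cn, mutations=cohort.mutations, mirna=cohort.mirna,
        )
        calls[cohort.name], summaries[cohort.name] = bccp.assign_subtypes(
            std_cohort, model, coverage_floor)

    surv = pooled_survival_frame(cohorts, calls)
    if five_year:
        surv = survival.censor_at(surv, 60.0)
    chi2, logrank_p = survival.logrank_test(
        surv["time"], surv["event"], surv["group"])
    strata = "cohort" if len(cohorts) > 1 else None
    covs = ["activated", "male", "age_ge_60", "oropharynx", "t4",
            "node_positive", "stage_34"]
    covs = [c for c in covs if surv[c].nunique() > 1]
    cox_results = survival.cox_fit(surv, covs, multivariate=False, strata=strata)
    cox_results += survival.cox_fit(surv, covs, multivariate=True, strata=strata)

    train_calls = calls[train.name]
    cn_screen = (associations.compare_cn_events(train, train_calls)
                 if train.cn is not None else None)
    mut_screen = None
    if train.mutations is not None:
        panel = mutation_panel or train.mutations.gene_ids
        mut_screen = associations.compare_mutations(train, train_calls, panel)
    mirna_screen = cni = None
    if train.mirna is not None:
        mirna_screen = associations.differential_mirna(train, train_calls)
        try:
            cni = associations.cni_mirna_screen(train, train_calls, driver)
        except ValueError as err:
            log.warning("CNI miRNA screen skipped: %s", err)
    hpv = None
    hpv_col = train.clinical.table.get("hpv_status")
    if hpv_col is not None:
        known = hpv_col[hpv_col.isin(["positive", "negative"])]
        try:
            hpv = associations.crosstab_subtype(train_calls, known)
        except ValueError as err:
            log.warning("HPV cross-tabulation skipped: %s", err)
    ifng = None
    try:
        scores = associations.ifng_score(standardize_genes(train.expression))
        ifng = associations.ifng_association(scores, train_calls)
    except ValueError as err:
        log.warning("IFNG analysis skipped: %s", err)

    return FullRunResult(
        signature_result=sig_result, model=model, calls=calls,
        summaries=summaries, loocv_rate=loocv_rate, survival_table=surv,
        logrank=(chi2, logrank_p), cox_results=cox_results,
        cn_screen=cn_screen, mutation_screen=mut_screen,
        mirna_screen=mirna_screen, cni_screen=cni,
        hpv_crosstab=hpv, ifng=ifng,
    )
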