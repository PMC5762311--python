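"""Survival comparisons between activation subtypes.

Thin, typed wrappers around lifelines: Kaplan-Meier product-limit curves
with Greenwood standard errors, the log-rank test, univariate and
multivariate Cox proportional-hazards models (Efron tie handling), and the
radiation subgroup battery with a subtype x radiation interaction test.

Pooled multi-cohort Cox models stratify the baseline hazard by cohort,
since cohorts differ in platform and follow-up.  Five-year analyses can
administratively censor follow-up at 60 months.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "KMCurve",
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "censor_at",
    "radiation_subgroup",
    "RadiationSubgroupResult",
]


@dataclass
class KMCurve:
    """Product-limit estimate with Greenwood standard errors."""

    times: np.ndarray        # distinct event/censor times, ascending
    at_risk: np.ndarray
    events: np.ndarray
    survival: np.ndarray     # S(t) just after each time
    greenwood_se: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t); step function, right-continuous (S(0)=1)."""
        if t < 0:
            raise ValueError("time must be non-negative")
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def se_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 0.0 if idx < 0 else float(self.greenwood_se[idx])


@dataclass
class CoxResult:
    covariate: str
    hazard_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    model_type: str  # "univariate" / "multivariate"
    n: int
    n_events: int


def _check_times(times: Sequence[float]) -> np.ndarray:
    t = np.asarray(times, dtype=float)
    if t.size == 0:
        raise ValueError("no survival records")
    if (t < 0).any():
        raise ValueError("negative survival time")
    return t


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Ties are handled by simultaneous decrement at the shared time.  With
    no events the curve is identically 1.
    """
    t = _check_times(times)
    e = np.asarray(events, dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table  # removed, observed, censored, entrance, at_risk
    tt = table.index.to_numpy(dtype=float)
    observed = table["observed"].to_numpy(dtype=float)
    at_risk = table["at_risk"].to_numpy(dtype=float)
    surv = (kmf.survival_function_["KM_estimate"]
            .reindex(table.index).to_numpy(dtype=float))
    with np.errstate(divide="ignore", invalid="ignore"):
        term = np.where(
            at_risk > observed, observed / (at_risk * (at_risk - observed)), 0.0
        )
    greenwood = surv * np.sqrt(np.cumsum(term))
    # drop lifelines' synthetic entrance row at t=0 when no one was removed there
    keep = ~((tt == 0) & (table["removed"].to_numpy() == 0))
    return KMCurve(
        times=tt[keep], at_risk=at_risk[keep], events=observed[keep],
        survival=surv[keep], greenwood_se=greenwood[keep],
    )


def logrank_test(
    times: Sequence[float], events: Sequence[int], groups: Sequence
) -> tuple[float, float]:
    """K-sample log-rank test; chi-square statistic and p on K-1 df."""
    t = _check_times(times)
    e = np.asarray(events, dtype=int)
    g = pd.Series(list(groups))
    counts = g.value_counts()
    if len(counts) < 2:
        raise ValueError("log-rank test needs at least two non-empty groups")
    res = multivariate_logrank_test(t, g.to_numpy(), e)
    return float(res.test_statistic), float(res.p_value)


def censor_at(
    df: pd.DataFrame, horizon: float, time_col: str = "time", event_col: str = "event"
) -> pd.DataFrame:
    """Administratively censor follow-up at ``horizon`` (e.g. 60 months
    for five-year analyses)."""
    out = df.copy()
    over = out[time_col] > horizon
    out.loc[over, time_col] = horizon
    out.loc[over, event_col] = 0
    return out


def _fit_cox(
    df: pd.DataFrame,
    covariates: Sequence[str],
    model_type: str,
    strata: Optional[str],
    time_col: str,
    event_col: str,
) -> list[CoxResult]:
    cols = [time_col, event_col, *covariates] + ([strata] if strata else [])
    data = df[cols].dropna()
    if int(data[event_col].sum()) == 0:
        raise ValueError("no events in the data")
    for cov in covariates:
        if data[cov].nunique() < 2:
            raise ValueError(f"covariate {cov!r} has no contrast")
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(data, duration_col=time_col, event_col=event_col,
                    strata=strata)
    except (ConvergenceError, np.linalg.LinAlgError) as err:
        raise ValueError(f"Cox fit failed for {list(covariates)}: {err}") from err
    out = []
    ci = cph.confidence_intervals_
    for cov in covariates:
        out.append(CoxResult(
            covariate=cov,
            hazard_ratio=float(np.exp(cph.params_[cov])),
            ci_low=float(np.exp(ci.loc[cov].iloc[0])),
            ci_high=float(np.exp(ci.loc[cov].iloc[1])),
            p_value=float(cph.summary.loc[cov, "p"]),
            model_type=model_type,
            n=int(data.shape[0]),
            n_events=int(data[event_col].sum()),
        ))
    return out


def cox_fit(
    df: pd.DataFrame,
    covariates: Sequence[str],
    multivariate: bool = False,
    strata: Optional[str] = None,
    time_col: str = "time",
    event_col: str = "event",
) -> list[CoxResult]:
    """Cox proportional-hazards regression (Efron tie correction).

    Covariates must be numeric (binary indicators coded 0/1 for factor
    contrasts).  ``multivariate=False`` fits one model per covariate;
    ``multivariate=True`` fits all jointly.  ``strata`` names a column
    (typically the cohort) by which the baseline hazard is stratified.
    """
    if not multivariate:
        results: list[CoxResult] = []
        for cov in covariates:
            results.extend(
                _fit_cox(df, [cov], "univariate", strata, time_col, event_col)
            )
        return results
    return _fit_cox(df, list(covariates), "multivariate", strata, time_col, event_col)


@dataclass
class RadiationSubgroupResult:
    """Log-rank p-values in the four subtype/radiation strata plus the
    interaction term from a Cox model with subtype, radiation and their
    product.  Comparisons with an empty stratum are None."""

    p_subtype_irradiated: Optional[float]
    p_subtype_nonirradiated: Optional[float]
    p_radiation_within_active: Optional[float]
    p_radiation_within_inactive: Optional[float]
    interaction: CoxResult


def radiation_subgroup(
    df: pd.DataFrame,
    time_col: str = "time",
    event_col: str = "event",
    group_col: str = "group",       # "YA"/"YI"
    radiation_col: str = "radiation",  # "yes"/"no"
) -> RadiationSubgroupResult:
    """Subgroup survival comparisons by radiation therapy.

    Runs the log-rank test for subtype within irradiated and
    non-irradiated patients and for radiation within each subtype, then a
    Cox model with subtype, radiation and subtype x radiation whose
    interaction term tests effect modification.
    """
    data = df[[time_col, event_col, group_col, radiation_col]].dropna()
    data = data[data[radiation_col].isin(["yes", "no"])]

    def _logrank(sub: pd.DataFrame, col: str) -> Optional[float]:
        if sub.empty or sub[col].nunique() < 2:
            warnings.warn("stratum empty or without contrast; comparison skipped")
            return None
        return logrank_test(sub[time_col], sub[event_col], sub[col])[1]

    p_irr = _logrank(data[data[radiation_col] == "yes"], group_col)
    p_nonirr = _logrank(data[data[radiation_col] == "no"], group_col)
    p_ya = _logrank(data[data[group_col] == "YA"], radiation_col)
    p_yi = _logrank(data[data[group_col] == "YI"], radiation_col)

    model = data.copy()
    model["subtype"] = (model[group_col] == "YA").astype(int)
    model["radiation_flag"] = (model[radiation_col] == "yes").astype(int)
    model["subtype_x_radiation"] = model["subtype"] * model["radiation_flag"]
    results = _fit_cox(
        model, ["subtype", "radiation_flag", "subtype_x_radiation"],
        "multivariate", None, time_col, event_col,
    )
    interaction = next(r for r in results if r.covariate == "subtype_x_radiation")
    return RadiationSubgroupResult(
        p_subtype_irradiated=p_irr,
        p_subtype_nonirradiated=p_nonirr,
        p_radiation_within_active=p_ya,
        p_radiation_within_inactive=p_yi,
        interaction=interaction,
    )
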