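"""Associations between patient-level H-scores and disease-specific
survival: Kaplan-Meier estimates, log-rank tests, Cox proportional-hazards
models (Efron ties), quartile/median splits and subgroup analysis.

The model fitting is delegated to lifelines; the wrappers enforce the
pipeline's preconditions and return plain-table results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "split_quartiles",
    "median_split",
    "subgroup_analysis",
]


@dataclass
class CoxResult:
    terms: list[str]
    coef: np.ndarray  # log-hazard per unit
    hazard_ratio: np.ndarray
    ci_low: np.ndarray  # 95% CI on the hazard-ratio scale
    ci_high: np.ndarray
    p_value: np.ndarray
    n: int
    n_events: int
    converged: bool = True

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "term": self.terms,
                "coef": self.coef,
                "hr": self.hazard_ratio,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.p_value,
                "n": self.n,
                "n_events": self.n_events,
            }
        )


def km_estimate(times, events) -> pd.DataFrame:
    """Product-limit survival estimate.

    Returns one row per distinct observed time with columns
    (time, survival, at_risk); survival starts at 1 and is non-increasing.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(t) == 0:
        raise ValueError("empty survival data")
    if np.any(t <= 0):
        raise ValueError("survival times must be positive")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    table = kmf.event_table
    sf = kmf.survival_function_["KM_estimate"]
    out = pd.DataFrame(
        {
            "time": table.index.to_numpy(dtype=float),
            "survival": sf.reindex(table.index).to_numpy(dtype=float),
            "at_risk": table["at_risk"].to_numpy(dtype=int),
        }
    )
    return out[out["time"] > 0].reset_index(drop=True)


def logrank_test(times, events, group) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p-value)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    g = np.asarray(group)
    labels = np.unique(g)
    if len(labels) != 2:
        raise ValueError("logrank_test requires exactly two groups")
    m0, m1 = g == labels[0], g == labels[1]
    if e[m0].sum() < 1 or e[m1].sum() < 1:
        raise ValueError("each group needs at least one event")
    res = _ll_logrank(t[m0], t[m1], event_observed_A=e[m0], event_observed_B=e[m1])
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    covariates: pd.DataFrame,
    times,
    events,
    max_steps: int = 50,
    tol: float = 1e-8,
) -> CoxResult:
    """Cox proportional-hazards fit (Efron tie handling, Newton updates).

    ``covariates`` is a numeric design frame, one column per term.  SEs
    come from the inverse observed information; CIs are Wald, exponentiated
    to the hazard-ratio scale.
    """
    cov = pd.DataFrame(covariates).reset_index(drop=True)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    if len(cov) != len(t) or len(t) != len(e):
        raise ValueError("covariates, times and events must align")
    for col in cov.columns:
        if np.ptp(cov[col].to_numpy(dtype=float)) == 0:
            raise ValueError(f"constant covariate: {col}")
    if e.sum() < len(cov.columns) + 1:
        raise ValueError("too few events for the number of covariates")
    df = cov.copy()
    df["__time"] = t
    df["__event"] = e.astype(int)
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(
                df,
                duration_col="__time",
                event_col="__event",
                fit_options={"step_size": 0.95, "max_steps": max_steps,
                             "precision": tol},
            )
        converged = True
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    summary = cph.summary
    return CoxResult(
        terms=list(summary.index),
        coef=summary["coef"].to_numpy(),
        hazard_ratio=summary["exp(coef)"].to_numpy(),
        ci_low=summary["exp(coef) lower 95%"].to_numpy(),
        ci_high=summary["exp(coef) upper 95%"].to_numpy(),
        p_value=summary["p"].to_numpy(),
        n=len(df),
        n_events=int(e.sum()),
        converged=converged,
    )


def split_quartiles(h_scores) -> np.ndarray:
    """Quartile labels 1-4 with cut-points from the combined input.

    Cut-points are the 25/50/75 empirical percentiles; ties go to the
    lower quartile (label = 1 + number of cut-points strictly below the
    value).  All-equal input degenerates to label 1 everywhere (warned).
    """
    v = np.asarray(h_scores, dtype=float)
    if len(v) < 8:
        raise ValueError("need at least 8 patients for quartiles")
    cuts = np.percentile(v, [25, 50, 75])
    labels = 1 + (v[:, None] > cuts[None, :]).sum(axis=1)
    if np.ptp(v) == 0:
        warnings.warn("degenerate quartile split: all values equal")
    return labels.astype(int)


def median_split(h_scores) -> np.ndarray:
    """Labels 'high' (strictly above the median) / 'low' (ties low)."""
    v = np.asarray(h_scores, dtype=float)
    if len(v) < 2:
        raise ValueError("need at least 2 patients for a median split")
    med = np.median(v)
    return np.where(v > med, "high", "low")


def subgroup_analysis(
    patients: pd.DataFrame,
    scores: pd.DataFrame,
    stratifier_marker: str,
    analyte_marker: str,
) -> dict[str, CoxResult]:
    """Median-split patients on the stratifier marker's H-score, then fit a
    univariable Cox model of the analyte H-score within each stratum.

    ``patients`` needs patient_id/time_months/event; ``scores`` is long
    format (patient_id, marker_id, h_score) covering both markers.
    """
    wide = scores.pivot_table(
        index="patient_id", columns="marker_id", values="h_score"
    )
    for m in (stratifier_marker, analyte_marker):
        if m not in wide.columns:
            raise ValueError(f"marker {m!r} missing from scores")
    merged = patients.merge(
        wide[[stratifier_marker, analyte_marker]].reset_index(),
        on="patient_id",
        how="inner",
    ).dropna(subset=[stratifier_marker, analyte_marker])
    if np.ptp(merged[stratifier_marker].to_numpy()) == 0:
        raise ValueError("constant stratifier: median split is empty")
    strata = median_split(merged[stratifier_marker].to_numpy())
    results = {}
    for label in ("low", "high"):
        sub = merged[strata == label]
        if sub["event"].sum() < 3:
            raise ValueError(f"stratum {label!r} has too few events")
        results[label] = cox_fit(
            sub[[analyte_marker]].rename(columns={analyte_marker: "h_score"}),
            sub["time_months"],
            sub["event"],
        )
    return results
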