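"""Event-free and overall survival: Kaplan–Meier, log-rank, Cox.

EFS events are relapse or death (whichever comes first); OS events are
deaths.  Burden groups for curve comparison are dichotomized at the cohort
median (ties to the low group).  Estimation is delegated to lifelines:
product-limit curves via ``KaplanMeierFitter``, the two-group log-rank test,
and the Cox proportional-hazards partial likelihood via ``CoxPHFitter``
(Efron tie handling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank

from .simulate import ClinicalRecord


@dataclass(frozen=True)
class SurvivalRecord:
    patient_id: str
    time: float  # months
    event: int  # 1 = event observed, 0 = censored
    endpoint: str  # "EFS" | "OS"

    def __post_init__(self) -> None:
        if self.time <= 0:
            raise ValueError(f"{self.patient_id}: non-positive time {self.time}")
        if self.event not in (0, 1):
            raise ValueError(f"{self.patient_id}: event must be 0/1")


@dataclass(frozen=True)
class KMEstimate:
    """Product-limit estimate tabulated at the distinct observed times."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    n_events: np.ndarray

    def survival_at(self, t: float) -> float:
        """S(t): right-continuous step function, S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass(frozen=True)
class CoxFit:
    coefficients: dict[str, float]
    standard_errors: dict[str, float]
    hazard_ratios: dict[str, float]
    converged: bool
    iterations: int | None = None


def survival_records(
    clinical: list[ClinicalRecord], endpoint: str
) -> list[SurvivalRecord]:
    """Extract one endpoint's (time, event) rows from the clinical table."""
    if endpoint not in ("EFS", "OS"):
        raise ValueError(f"unknown endpoint {endpoint!r}")
    out = []
    for r in clinical:
        t = r.efs_time if endpoint == "EFS" else r.os_time
        e = r.efs_event if endpoint == "EFS" else r.os_event
        out.append(
            SurvivalRecord(patient_id=r.patient_id, time=t, event=e, endpoint=endpoint)
        )
    return out


def km_estimate(records: list[SurvivalRecord]) -> KMEstimate:
    """Kaplan–Meier product-limit estimator.

    The returned table has one row per distinct observed time (event or
    censoring); the survival column decreases only at event times and with
    no censoring equals the empirical survival fraction.
    """
    if not records:
        raise ValueError("need at least one record")
    times = np.array([r.time for r in records], dtype=float)
    events = np.array([r.event for r in records], dtype=int)
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    # event_table opens with a t=0 row holding no observations; drop it
    table = kmf.event_table[kmf.event_table.index > 0]
    ts = table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(ts).to_numpy(dtype=float)
    return KMEstimate(
        times=ts,
        survival=surv,
        at_risk=table["at_risk"].to_numpy(dtype=int),
        n_events=table["observed"].to_numpy(dtype=int),
    )


def logrank_test(
    group_a: list[SurvivalRecord], group_b: list[SurvivalRecord]
) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square statistic, p).

    Raises ``ValueError`` when the pooled data contain no events (the test
    statistic is undefined).
    """
    if not group_a or not group_b:
        raise ValueError("both groups must be non-empty")
    ev = sum(r.event for r in group_a) + sum(r.event for r in group_b)
    if ev == 0:
        raise ValueError("no events in pooled data; log-rank not computable")
    res = _ll_logrank(
        np.array([r.time for r in group_a]),
        np.array([r.time for r in group_b]),
        event_observed_A=np.array([r.event for r in group_a]),
        event_observed_B=np.array([r.event for r in group_b]),
    )
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    times: np.ndarray,
    events: np.ndarray,
    covariates: pd.DataFrame,
) -> CoxFit:
    """Cox proportional-hazards fit of one or more covariates.

    Maximizes the partial likelihood (Efron ties) via lifelines.  Monotone
    likelihoods (perfect separation) are flagged as non-converged rather than
    reported as estimates.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if events.sum() < 2:
        raise ValueError("need at least 2 events to fit a Cox model")
    for col in covariates.columns:
        if covariates[col].nunique() < 2:
            raise ValueError(f"covariate {col!r} is constant")
    df = covariates.copy()
    df["_time"] = times
    df["_event"] = events
    cph = CoxPHFitter()
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            cph.fit(df, duration_col="_time", event_col="_event")
    except (ConvergenceError, np.linalg.LinAlgError, ValueError):
        return CoxFit(
            coefficients={}, standard_errors={}, hazard_ratios={}, converged=False
        )
    return CoxFit(
        coefficients=cph.params_.to_dict(),
        standard_errors=cph.standard_errors_.to_dict(),
        hazard_ratios=np.exp(cph.params_).to_dict(),
        converged=True,
    )


def median_split_labels(values: np.ndarray) -> np.ndarray:
    """"low" (<= cohort median) vs "high" labels for burden dichotomization."""
    vals = np.asarray(values, dtype=float)
    med = float(np.median(vals))
    return np.where(vals <= med, "low", "high")
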