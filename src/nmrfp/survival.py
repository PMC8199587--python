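"""Survival analysis for the metabolomic risk stratification.

Kaplan-Meier estimation, log-rank comparison, reverse-Kaplan-Meier median
follow-up, and Cox proportional-hazards modelling (Efron tie handling)
with bidirectional stepwise covariate selection (p < 0.05 to enter and to
stay).  Estimation is delegated to lifelines; this module fixes the
endpoint conventions, complete-case bookkeeping and the selection loop.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test


@dataclass
class KMCurve:
    """Product-limit estimate evaluated at the distinct event times."""

    times: np.ndarray  # ascending event times
    at_risk: np.ndarray
    n_events: np.ndarray
    survival: np.ndarray
    variance: np.ndarray  # Greenwood

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); S(0) = 1."""
        idx = np.searchsorted(self.times, t, side="right")
        return 1.0 if idx == 0 else float(self.survival[idx - 1])

    def median(self) -> float:
        """Smallest event time with S(t) <= 0.5, or inf if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if below.size else float("inf")


def km_estimate(times: Sequence[float], events: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimator with Greenwood variance.

    At tied times, events are handled before censorings (the standard
    convention: censored-at-t subjects are still at risk for events at t).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise ValueError("need at least one observation")
    if np.any(times < 0):
        raise ValueError("negative survival time")
    kmf = KaplanMeierFitter().fit(times, events)
    table = kmf.event_table
    obs = table["observed"].to_numpy()
    at_risk = table["at_risk"].to_numpy()
    t = table.index.to_numpy(dtype=float)
    keep = obs > 0
    d, n, t = obs[keep], at_risk[keep], t[keep]
    surv = np.cumprod(1.0 - d / n)
    gw_terms = np.cumsum(d / (n * (n - d).clip(min=1)))
    var = np.where(surv > 0, surv**2 * gw_terms, 0.0)
    return KMCurve(times=t, at_risk=n, n_events=d, survival=surv, variance=var)


def logrank_test(groups: Sequence[tuple[Sequence[float], Sequence[int]]]) -> tuple[float, float]:
    """Log-rank comparison of two or more groups -> (chi-square, p).

    ``groups`` is a sequence of (times, events) pairs; df = n_groups - 1.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    times, events, labels = [], [], []
    for gi, (t, e) in enumerate(groups):
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
        if t.size == 0:
            raise ValueError(f"group {gi} is empty")
        times.append(t)
        events.append(e)
        labels.append(np.full(t.size, gi))
    times = np.concatenate(times)
    events = np.concatenate(events)
    labels = np.concatenate(labels)
    if events.sum() == 0:
        raise ValueError("no events in any group")
    res = multivariate_logrank_test(times, labels, events)
    return float(res.test_statistic), float(res.p_value)


def reverse_km_median_followup(times: Sequence[float], death_events: Sequence[int]) -> float:
    """Median follow-up by reverse Kaplan-Meier (censoring becomes the event).

    Returns inf when the reversed curve never crosses 0.5 (e.g. everyone died).
    """
    times = np.asarray(times, dtype=float)
    death_events = np.asarray(death_events, dtype=int)
    flipped = 1 - death_events
    if flipped.sum() == 0:
        return float("inf")
    return km_estimate(times, flipped).median()


@dataclass
class CoxResult:
    """Cox fit summary: per-covariate log-HR, HR, Wald CI and p."""

    table: pd.DataFrame  # index: covariate; columns: log_hr, hr, ci_low, ci_high, p
    n_complete: int
    n_events: int
    selected: list[str] = field(default_factory=list)

    @property
    def covariates(self) -> list[str]:
        return list(self.table.index)


def cox_fit(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    covariates: Sequence[str] | None = None,
) -> CoxResult:
    """Cox proportional-hazards fit on complete cases (Efron tie handling).

    Rows with missing values in the used columns are dropped and the
    complete-case count reported.  Constant covariates raise.
    """
    if covariates is None:
        covariates = [c for c in data.columns if c not in (duration_col, event_col)]
    covariates = list(covariates)
    if not covariates:
        raise ValueError("no covariates given")
    cols = [duration_col, event_col, *covariates]
    df = data[cols].dropna()
    n_complete = len(df)
    n_events = int(df[event_col].sum())
    if n_complete < 2 or n_events < 1:
        raise ValueError(f"too few complete cases ({n_complete}) or events ({n_events})")
    for c in covariates:
        if df[c].nunique() < 2:
            raise ValueError(f"covariate {c!r} is constant on complete cases")
    cph = CoxPHFitter()
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # lifelines convergence chatter on separation
        cph.fit(df, duration_col=duration_col, event_col=event_col)
    summ = cph.summary
    table = pd.DataFrame(
        {
            "log_hr": summ["coef"],
            "hr": summ["exp(coef)"],
            "ci_low": summ["exp(coef) lower 95%"],
            "ci_high": summ["exp(coef) upper 95%"],
            "p": summ["p"],
        }
    )
    table.index.name = "covariate"
    return CoxResult(table=table, n_complete=n_complete, n_events=n_events,
                     selected=covariates)


def stepwise_cox(
    data: pd.DataFrame,
    duration_col: str,
    event_col: str,
    candidates: Sequence[str],
    p_enter: float = 0.05,
    p_stay: float = 0.05,
) -> CoxResult:
    """Bidirectional stepwise Cox selection (enter and stay at p < 0.05).

    Forward step: among candidates not yet in the model, add the one with the
    smallest Wald p below ``p_enter`` (ties broken by candidate order).
    Backward step: after each entry, drop any retained covariate whose Wald p
    is at or above ``p_stay``.  Deterministic; returns the final model fit on
    complete cases for the selected covariates (empty table if none enter).
    """
    candidates = list(dict.fromkeys(candidates))  # dedupe, keep order
    if not candidates:
        raise ValueError("need at least one candidate covariate")
    selected: list[str] = []
    while True:
        best_p, best_c = None, None
        for c in candidates:
            if c in selected:
                continue
            try:
                res = cox_fit(data, duration_col, event_col, selected + [c])
            except ValueError:
                continue
            p = float(res.table.loc[c, "p"])
            if p < p_enter and (best_p is None or p < best_p):
                best_p, best_c = p, c
        if best_c is None:
            break
        selected.append(best_c)
        # backward pruning until all retained covariates satisfy the stay rule
        while True:
            res = cox_fit(data, duration_col, event_col, selected)
            worst = res.table["p"].idxmax()
            if float(res.table.loc[worst, "p"]) >= p_stay and len(selected) > 0:
                selected.remove(worst)
                if not selected:
                    break
            else:
                break
        if not selected:
            break
    if not selected:
        empty = pd.DataFrame(columns=["log_hr", "hr", "ci_low", "ci_high", "p"])
        empty.index.name = "covariate"
        return CoxResult(table=empty, n_complete=len(data.dropna(subset=[duration_col, event_col])),
                         n_events=int(data[event_col].dropna().sum()), selected=[])
    final = cox_fit(data, duration_col, event_col, selected)
    final.selected = list(selected)
    return final
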