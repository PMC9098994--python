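"""Kaplan-Meier estimation, log-rank testing and Cox proportional-hazards models.

Thin, typed wrappers over lifelines with the conventions fixed: Efron
handling of tied event times in the Cox partial likelihood, Wald confidence
intervals and p-values per covariate, and stage entering models as the
binary contrast II+III vs I. Continuous expression covariates should be
standardized to unit variance by the caller so hazard ratios read "per SD".
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test as _ll_logrank
from lifelines.statistics import multivariate_logrank_test

__all__ = [
    "KMCurve",
    "CoxFit",
    "km_estimate",
    "logrank_test",
    "cox_fit",
    "bivariate_scan",
    "stratified_km_report",
]


@dataclass(frozen=True)
class KMCurve:
    """Product-limit survival estimate."""

    times: np.ndarray            # distinct observed times, ascending
    survival: np.ndarray         # S(t) just after each time
    at_risk: np.ndarray          # number at risk just before each time
    median: float                # smallest time with S(t) <= 0.5 (inf if never)

    def survival_at(self, t: float) -> float:
        i = int(np.searchsorted(self.times, t, "right")) - 1
        return 1.0 if i < 0 else float(self.survival[i])


@dataclass(frozen=True)
class CoxFit:
    """Per-covariate hazard ratios with Wald CIs from one Cox model."""

    summary: pd.DataFrame        # index covariate; hr, ci_lower, ci_upper, p_value, coef
    log_likelihood: float
    n: int
    n_events: int

    def hr(self, covariate: str) -> float:
        return float(self.summary.loc[covariate, "hr"])


def _validate(time, event) -> tuple[np.ndarray, np.ndarray]:
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.size == 0:
        raise ValueError("no samples")
    if (time < 0).any():
        raise ValueError("negative survival time")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event flags must be 0/1")
    return time, event


def km_estimate(time: Sequence[float], event: Sequence[int]) -> KMCurve:
    """Kaplan-Meier product-limit estimate (events precede ties' censorings)."""
    time, event = _validate(time, event)
    kmf = KaplanMeierFitter()
    kmf.fit(time, event)
    times = kmf.event_table.index.to_numpy(dtype=float)
    surv = kmf.survival_function_["KM_estimate"].reindex(kmf.event_table.index).to_numpy()
    at_risk = kmf.event_table["at_risk"].to_numpy(dtype=int)
    # drop the t=0 anchor row lifelines inserts when no observation is at 0
    if times.size and times[0] == 0 and 0.0 not in time:
        times, surv, at_risk = times[1:], surv[1:], at_risk[1:]
    median = float(kmf.median_survival_time_)
    return KMCurve(times=times, survival=surv, at_risk=at_risk, median=median)


def logrank_test(
    time_a: Sequence[float], event_a: Sequence[int],
    time_b: Sequence[float], event_b: Sequence[int],
) -> float:
    """Two-sided p of the two-group log-rank chi-square (df=1)."""
    ta, ea = _validate(time_a, event_a)
    tb, eb = _validate(time_b, event_b)
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test undefined with zero events")
    return float(_ll_logrank(ta, tb, ea, eb).p_value)


def cox_fit(
    data: pd.DataFrame,
    covariates: Sequence[str],
    time_col: str = "time",
    event_col: str = "event",
    alpha: float = 0.05,
) -> CoxFit:
    """Cox proportional-hazards fit (Efron ties) with Wald CIs.

    Rows with a missing value in the time, event or any covariate column are
    dropped pairwise, never imputed.
    """
    cols = [time_col, event_col, *covariates]
    df = data[cols].dropna().astype(float)
    _validate(df[time_col], df[event_col])
    if int(df[event_col].sum()) == 0:
        raise ValueError("no events in the data")
    for cov in covariates:
        if df[cov].nunique() < 2:
            raise ValueError(f"covariate {cov!r} is constant after dropping missing")
    cph = CoxPHFitter(alpha=alpha)
    try:
        cph.fit(df, duration_col=time_col, event_col=event_col)
    except ConvergenceError as exc:
        raise RuntimeError(f"Cox model failed to converge: {exc}") from exc
    s = cph.summary
    summary = pd.DataFrame(
        {
            "coef": s["coef"],
            "hr": s["exp(coef)"],
            "ci_lower": s[f"exp(coef) lower {100 * (1 - alpha):g}%"],
            "ci_upper": s[f"exp(coef) upper {100 * (1 - alpha):g}%"],
            "p_value": s["p"],
        }
    )
    summary.index.name = "covariate"
    return CoxFit(
        summary=summary,
        log_likelihood=float(cph.log_likelihood_),
        n=int(df.shape[0]),
        n_events=int(df[event_col].sum()),
    )


def bivariate_scan(
    data: pd.DataFrame,
    fixed: str,
    others: Sequence[str],
    time_col: str = "time",
    event_col: str = "event",
) -> pd.DataFrame:
    """One two-covariate Cox model per (fixed, other) pair.

    Reports the fixed covariate's HR/CI/p from each model — the adjusted
    effect of the fixed variable given one potential confounder at a time.
    """
    rows = []
    for other in others:
        if other == fixed:
            raise ValueError("confounder identical to the fixed covariate")
        if data[[fixed, other]].dropna().corr().iloc[0, 1] > 1 - 1e-12:
            raise ValueError(f"covariate {other!r} collinear with {fixed!r}")
        fit = cox_fit(data, [fixed, other], time_col=time_col, event_col=event_col)
        row = fit.summary.loc[fixed].to_dict()
        row["adjusted_for"] = other
        row["n"] = fit.n
        rows.append(row)
    out = pd.DataFrame(rows)
    if not out.empty:
        out = out.set_index("adjusted_for")
    return out


def stratified_km_report(
    time: Sequence[float],
    event: Sequence[int],
    strata: Sequence[str],
) -> tuple[dict[str, KMCurve], float, pd.DataFrame]:
    """KM curve per stratum, global log-rank p, and pairwise log-rank table.

    Strata with no samples are dropped; at least two non-empty strata with
    at least one event overall are required.
    """
    time, event = _validate(time, event)
    strata = np.asarray(strata)
    labels = [s for s in dict.fromkeys(strata)]
    if len(labels) < 2:
        raise ValueError("need at least two strata")
    curves = {
        lab: km_estimate(time[strata == lab], event[strata == lab]) for lab in labels
    }
    global_p = float(multivariate_logrank_test(time, strata, event).p_value)
    pairs = []
    for a, b in itertools.combinations(labels, 2):
        ma, mb = strata == a, strata == b
        if event[ma].sum() + event[mb].sum() == 0:
            p = float("nan")
        else:
            p = logrank_test(time[ma], event[ma], time[mb], event[mb])
        pairs.append({"stratum_a": a, "stratum_b": b, "p_value": p})
    return curves, global_p, pd.DataFrame(pairs)
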