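"""Survival validation: Kaplan-Meier, log-rank, univariate Cox, tertiles.

Predicted R/CCR groups (or expression tertiles of a single gene) are
compared on relapse-free survival: time from diagnosis to relapse, with
CCR patients censored at last follow-up. Estimation and testing are done
with lifelines (product-limit estimator, two-group log-rank chi-square
with 1 df, Cox partial likelihood with Efron tie handling).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank

__all__ = [
    "CoxResult",
    "km_estimate",
    "logrank_test",
    "cox_univariate",
    "tertile_groups",
    "format_p",
]


@dataclass
class CoxResult:
    """Univariate Cox fit: hazard ratio per covariate unit, 95% Wald CI,
    Wald p. ``flagged`` marks monotone-likelihood (perfectly ordering)
    covariates, where the HR diverges."""

    hazard_ratio: float
    ci_low: float
    ci_high: float
    p: float
    flagged: bool = False

    def __post_init__(self):
        if not (self.ci_low <= self.hazard_ratio <= self.ci_high):
            raise ValueError("CI must bracket the hazard ratio")


def _times_events(records) -> tuple[np.ndarray, np.ndarray]:
    if isinstance(records, pd.DataFrame):
        t = records["time_years"].to_numpy(dtype=float)
        e = records["event"].to_numpy(dtype=int)
    else:
        t, e = records
        t = np.asarray(t, dtype=float)
        e = np.asarray(e, dtype=int)
    if t.size == 0:
        raise ValueError("no survival records")
    if (t <= 0).any():
        raise ValueError("times must be positive")
    return t, e


def km_estimate(records) -> pd.DataFrame:
    """Product-limit survival curve.

    ``records`` is a clinical DataFrame (time_years, event) or a
    ``(times, events)`` pair. Returns a step-function table with columns
    ``time``, ``survival``, ``at_risk`` at the distinct observed times
    (events at a time are handled before censorings, the standard
    product-limit convention).
    """
    t, e = _times_events(records)
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    surv = kmf.survival_function_["KM_estimate"]
    at_risk = kmf.event_table["at_risk"].reindex(surv.index)
    return pd.DataFrame(
        {"time": surv.index.to_numpy(), "survival": surv.to_numpy(),
         "at_risk": at_risk.to_numpy()}
    )


def logrank_test(group_a, group_b) -> float:
    """Two-group log-rank p-value (chi-square, 1 df). Returns 1.0 when no
    events occur in either group."""
    ta, ea = _times_events(group_a)
    tb, eb = _times_events(group_b)
    if ea.sum() + eb.sum() == 0:
        return 1.0
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return float(res.p_value)


def cox_univariate(covariate, records) -> CoxResult:
    """Cox proportional-hazards fit of one continuous covariate."""
    t, e = _times_events(records)
    x = np.asarray(covariate, dtype=float)
    if x.shape[0] != t.shape[0]:
        raise ValueError("covariate must align with records")
    if np.ptp(x) == 0:
        raise ValueError("covariate has no variation")
    df = pd.DataFrame({"time": t, "event": e, "x": x})
    cph = CoxPHFitter()
    flagged = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        cph.fit(df, duration_col="time", event_col="event")
        flagged = any("convergence" in str(w.message).lower() or
                      "monotone" in str(w.message).lower() for w in caught)
    s = cph.summary.loc["x"]
    return CoxResult(
        hazard_ratio=float(s["exp(coef)"]),
        ci_low=float(s["exp(coef) lower 95%"]),
        ci_high=float(s["exp(coef) upper 95%"]),
        p=float(s["p"]),
        flagged=flagged,
    )


def tertile_groups(values) -> np.ndarray:
    """Split values at the empirical 33.3/66.7 percentiles into labels
    'low', 'mid', 'high'; ties at a boundary go to the lower tertile."""
    x = np.asarray(values, dtype=float)
    if np.unique(x).size < 3:
        raise ValueError("need >= 3 distinct values for tertiles")
    q1, q2 = np.quantile(x, [1 / 3, 2 / 3])
    return np.where(x <= q1, "low", np.where(x <= q2, "mid", "high"))


def format_p(p: float) -> str:
    """Table-style p formatting: values below 1e-4 print as '<0.0001'."""
    return "<0.0001" if p < 1e-4 else f"{p:.3g}"
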