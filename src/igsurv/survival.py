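"""Survival estimation and association statistics.

Kaplan-Meier curves, the two-group log-rank test, Cox proportional-hazards
fits (univariate on a median-split indicator and multivariable with clinical
covariates), Bonferroni adjustment across the subgroup screen, and Spearman
rank correlation.  The estimators are backed by lifelines and scipy; this
module fixes the conventions used throughout the analysis (Efron tie
handling, high = 1 coding so HR < 1 means the high group survives longer).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines import statistics as lls
from lifelines.exceptions import ConvergenceWarning
from scipy import stats

__all__ = [
    "KMCurve",
    "CoxModel",
    "SurvivalComparison",
    "km_curve",
    "logrank_test",
    "cox_fit",
    "cox_score_test",
    "bonferroni_adjust",
    "spearman_corr",
    "compare_survival",
]

logger = logging.getLogger(__name__)


@dataclass
class KMCurve:
    """Product-limit estimate of the survival function."""

    times: np.ndarray                 # distinct observed times, ascending
    survival: np.ndarray              # S(t) at those times
    at_risk: np.ndarray               # number at risk entering each time
    events: np.ndarray                # deaths at each time
    censored: np.ndarray              # censorings at each time

    def survival_at(self, t: float) -> float:
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "time": self.times,
                "survival": self.survival,
                "at_risk": self.at_risk,
                "events": self.events,
                "censored": self.censored,
            }
        )


@dataclass
class CoxModel:
    """Cox proportional-hazards fit (partial likelihood, Efron ties)."""

    covariates: list[str]
    coef: pd.Series                   # log-hazard units
    se: pd.Series
    hazard_ratios: pd.Series          # exp(coef)
    p_values: pd.Series
    ci_lower: pd.Series               # 95% CI on the hazard ratio
    ci_upper: pd.Series
    converged: bool
    n: int
    n_dropped: int


@dataclass
class SurvivalComparison:
    """High-vs-low comparison of one metric within one patient subgroup."""

    n_high: int
    n_low: int
    km_high: KMCurve
    km_low: KMCurve
    chi2: float
    p: float
    adjusted_p: float
    hazard_ratio: float               # high vs low; < 1 favors the high group
    ci_lower: float
    ci_upper: float


def km_curve(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimator.

    Subjects censored at an event time are counted in the risk set at that
    time (the standard convention: censoring happens just after events).
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=bool)
    if times.size == 0:
        raise ValueError("empty survival data")
    if (times <= 0).any():
        raise ValueError("survival times must be strictly positive")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tab = kmf.event_table
    tab = tab[tab.index > 0]  # drop the synthetic t=0 row
    t = tab.index.to_numpy(dtype=float)
    surv = kmf.survival_function_at_times(t).to_numpy()
    return KMCurve(
        times=t,
        survival=surv,
        at_risk=tab["at_risk"].to_numpy(),
        events=tab["observed"].to_numpy(),
        censored=tab["censored"].to_numpy(),
    )


def logrank_test(times_a, events_a, times_b, events_b) -> tuple[float, float]:
    """Two-group log-rank test; returns (chi-square with 1 df, p-value)."""
    events_a = np.asarray(events_a, dtype=bool)
    events_b = np.asarray(events_b, dtype=bool)
    if len(times_a) == 0 or len(times_b) == 0:
        raise ValueError("both groups must be non-empty")
    if not events_a.any() and not events_b.any():
        raise ValueError("log-rank test undefined with no events in either group")
    res = lls.logrank_test(times_a, times_b, event_observed_A=events_a,
                           event_observed_B=events_b)
    return float(res.test_statistic), float(res.p_value)


def cox_fit(
    covariates: pd.DataFrame,
    times,
    events,
    robust: bool = False,
) -> CoxModel:
    """Multivariable (or univariate) Cox PH fit with Efron tie handling.

    Rows with any missing covariate are dropped (the count is logged).
    Non-convergence is flagged on the returned model, never silent; complete
    separation surfaces as a lifelines convergence error.
    """
    df = covariates.copy()
    df["_time"] = np.asarray(times, dtype=float)
    df["_event"] = np.asarray(events, dtype=bool)
    n_total = len(df)
    df = df.dropna()
    n_dropped = n_total - len(df)
    if n_dropped:
        logger.info("cox_fit: dropped %d/%d rows with missing covariates",
                    n_dropped, n_total)
    cph = CoxPHFitter()
    converged = True
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", ConvergenceWarning)
        cph.fit(df, duration_col="_time", event_col="_event", robust=robust)
        converged = not any(issubclass(w.category, ConvergenceWarning) for w in caught)
    summ = cph.summary
    return CoxModel(
        covariates=list(summ.index),
        coef=summ["coef"],
        se=summ["se(coef)"],
        hazard_ratios=summ["exp(coef)"],
        p_values=summ["p"],
        ci_lower=np.exp(summ["coef lower 95%"]),
        ci_upper=np.exp(summ["coef upper 95%"]),
        converged=converged,
        n=len(df),
        n_dropped=n_dropped,
    )


def cox_score_test(group, times, events) -> float:
    """Cox partial-likelihood score statistic at beta = 0 for one covariate.

    Computed directly from risk-set moments: U = sum over deaths of
    (x_i - mean x over the risk set), I = sum over deaths of the risk-set
    variance of x; the statistic is U^2 / I.  For a binary covariate with
    untied event times this equals the log-rank chi-square.
    """
    x = np.asarray(group, dtype=float)
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=bool)
    u = 0.0
    info = 0.0
    for ti in np.unique(t[e]):
        at_risk = t >= ti
        xbar = x[at_risk].mean()
        x2bar = (x[at_risk] ** 2).mean()
        dead = e & (t == ti)
        u += (x[dead] - xbar).sum()
        info += dead.sum() * (x2bar - xbar**2)
    if info <= 0:
        raise ValueError("zero information: covariate constant on all risk sets")
    return float(u * u / info)


def bonferroni_adjust(p: float, m: int) -> float:
    """min(1, p * m) for a family of m tests."""
    if not 0 <= p <= 1:
        raise ValueError(f"p-value out of range: {p}")
    if m < 1:
        raise ValueError(f"family size must be >= 1, got {m}")
    return min(1.0, p * m)


def spearman_corr(x, y) -> tuple[float, float]:
    """Spearman rank correlation with mid-rank ties; large-sample p-value."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    ok = ~(np.isnan(x) | np.isnan(y))
    x, y = x[ok], y[ok]
    if x.size < 4:
        raise ValueError(f"spearman_corr needs >= 4 paired values, got {x.size}")
    if np.all(x == x[0]) or np.all(y == y[0]):
        raise ValueError("spearman correlation undefined for a constant vector")
    rho, p = stats.spearmanr(x, y)
    return float(rho), float(p)


def compare_survival(
    labels: pd.Series,
    times: pd.Series,
    events: pd.Series,
    family_size: int = 12,
) -> SurvivalComparison:
    """KM curves, log-rank and univariate Cox HR for a high/low median split.

    ``labels`` are the output of a median split ({high, low, excluded});
    the hazard ratio is from a Cox fit on the high indicator (high = 1), so
    HR < 1 means the high group lives longer.  The raw log-rank p is
    Bonferroni-adjusted for ``family_size`` parallel subgroup tests.
    """
    keep = labels.isin(["high", "low"])
    lab = labels[keep]
    t = times.loc[lab.index]
    e = events.loc[lab.index]
    hi = lab == "high"
    km_hi = km_curve(t[hi], e[hi])
    km_lo = km_curve(t[~hi], e[~hi])
    chi2, p = logrank_test(t[hi], e[hi], t[~hi], e[~hi])
    cox = cox_fit(pd.DataFrame({"high": hi.astype(float)}), t, e)
    return SurvivalComparison(
        n_high=int(hi.sum()),
        n_low=int((~hi).sum()),
        km_high=km_hi,
        km_low=km_lo,
        chi2=chi2,
        p=p,
        adjusted_p=bonferroni_adjust(p, family_size),
        hazard_ratio=float(cox.hazard_ratios["high"]),
        ci_lower=float(cox.ci_lower["high"]),
        ci_upper=float(cox.ci_upper["high"]),
    )
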