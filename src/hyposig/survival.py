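"""Survival evaluation of the hypoxia call.

Kaplan–Meier curves, the log-rank test and Cox proportional-hazards
models (Efron tie handling, Wald inference) are provided by lifelines
behind this module's interface. Follow-up is censored at a horizon (5
years = 60 months by default) before modelling; adjusters enter the
multivariable model only if their univariable p is below the screening
threshold, while the exposure of interest is always retained. A
Wilcoxon rank-sum comparison (exact for small samples) supports
group-level score contrasts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .errors import AnalysisError
from .io import ClinicalTable

logger = logging.getLogger(__name__)

DAYS_PER_MONTH = 365.25 / 12.0
FIVE_YEARS_MONTHS = 60.0


@dataclass
class CoxResult:
    """Per-covariate hazard ratios with Wald inference."""

    table: pd.DataFrame  # index covariate; beta, hr, ci_low, ci_high, p
    log_likelihood: float
    n: int
    n_events: int

    def hr(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "hr"])

    def p(self, covariate: str) -> float:
        return float(self.table.loc[covariate, "p"])


@dataclass
class KMCurve:
    """Right-continuous product-limit survival estimate."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray

    def at(self, t: float) -> float:
        """S(t): survival just after the last event time <= t."""
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


@dataclass
class LogrankResult:
    statistic: float
    p: float
    df: int = 1


def censor_at(clinical: ClinicalTable,
              horizon: float = FIVE_YEARS_MONTHS) -> ClinicalTable:
    """Administratively censor follow-up at ``horizon`` months."""
    if horizon <= 0:
        raise AnalysisError("censoring horizon must be positive")
    df = clinical.data.copy()
    late = df["time"] > horizon
    df.loc[late, "event"] = 0
    df.loc[late, "time"] = horizon
    return ClinicalTable(df)


def kaplan_meier(times, events) -> KMCurve:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    if times.size == 0:
        raise AnalysisError("no samples")
    if (times < 0).any():
        raise AnalysisError("negative follow-up times")
    kmf = KaplanMeierFitter()
    kmf.fit(times, events)
    event_times = np.asarray(kmf.event_table.index, dtype=float)
    surv = kmf.survival_function_["KM_estimate"].to_numpy()
    at_risk = kmf.event_table["at_risk"].to_numpy()
    return KMCurve(times=event_times, survival=surv, at_risk=at_risk)


def logrank(times, events, group) -> LogrankResult:
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    group = np.asarray(group)
    levels = np.unique(group)
    if levels.size != 2:
        raise AnalysisError("log-rank comparison needs exactly two groups")
    a = group == levels[0]
    if a.sum() == 0 or (~a).sum() == 0:
        raise AnalysisError("one group is empty")
    res = logrank_test(times[a], times[~a], events[a], events[~a])
    return LogrankResult(statistic=float(res.test_statistic),
                         p=float(res.p_value))


def cox_fit(clinical: ClinicalTable, covariates: list[str]) -> CoxResult:
    """Cox PH fit (Efron ties) returning Wald HRs, CIs and p-values.

    Constant covariates are dropped with a warning; a fit that fails to
    converge raises with the covariate lifelines identifies.
    """
    df = clinical.data[["time", "event", *covariates]].dropna()
    if df["event"].sum() < 1:
        raise AnalysisError("no events in the data")
    usable = []
    for c in covariates:
        if df[c].nunique() < 2:
            logger.warning("dropping constant covariate %r", c)
        else:
            usable.append(c)
    if not usable:
        raise AnalysisError("no covariate with variation")
    cph = CoxPHFitter()
    try:
        cph.fit(df[["time", "event", *usable]], duration_col="time",
                event_col="event", fit_options={"precision": 1e-10})
    except Exception as exc:  # lifelines raises ConvergenceError subclasses
        raise AnalysisError(f"Cox fit failed: {exc}") from exc
    summ = cph.summary
    table = pd.DataFrame({
        "beta": summ["coef"],
        "hr": summ["exp(coef)"],
        "ci_low": np.exp(summ["coef lower 95%"]),
        "ci_high": np.exp(summ["coef upper 95%"]),
        "p": summ["p"],
    })
    table.index.name = "covariate"
    return CoxResult(table=table, log_likelihood=float(cph.log_likelihood_),
                     n=len(df), n_events=int(df["event"].sum()))


def univariable_screen(clinical: ClinicalTable, candidates: list[str],
                       alpha: float = 0.05,
                       always_include: str | None = None) -> list[str]:
    """Adjusters with univariable Cox p < alpha.

    ``always_include`` (the exposure of interest, e.g. the hypoxia call)
    bypasses screening and leads the returned list.
    """
    if not candidates:
        raise AnalysisError("no candidate covariates")
    selected = []
    for c in candidates:
        if c == always_include:
            continue
        res = cox_fit(clinical, [c])
        if c in res.table.index and res.p(c) < alpha:
            selected.append(c)
    if always_include is not None:
        selected = [always_include] + selected
    return selected


def wilcoxon_rank_sum(x, y, alternative: str = "two-sided",
                      exact_max_n: int = 12) -> tuple[float, float]:
    """Mann–Whitney U with tie correction; exact null for small samples."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise AnalysisError("empty input sample")
    method = "exact" if x.size + y.size <= exact_max_n else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=alternative, method=method)
    return float(res.statistic), float(res.pvalue)
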