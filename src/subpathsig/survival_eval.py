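"""Survival evaluation: Kaplan-Meier, log-rank, Cox models, time-dependent ROC.

Groups produced by the risk-score signature are compared with the standard
two-group log-rank test and Kaplan-Meier product-limit curves (median
survival = earliest time with S(t) <= 0.5). Independence from clinical
covariates is assessed by multivariate Cox regression with backward stepwise
elimination (drop the largest Wald p > 0.05, refit, repeat). Discrimination
at a fixed horizon uses the cumulative-case / dynamic-control AUC with
inverse-probability-of-censoring weights (IPCW, Uno-type estimator), which
reduces exactly to the Mann-Whitney statistic when no subject is censored
before the horizon.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.statistics import logrank_test
from scipy import stats

from .activity_search import ActivityMatrix
from .expression_io import ClinicalTable
from .signature import HIGH, LOW, RiskScoreTable

logger = logging.getLogger(__name__)

__all__ = [
    "KMCurve",
    "logrank",
    "km_curve",
    "multivariate_cox_backward",
    "td_roc",
    "compare_auc",
    "activity_correlation",
    "stratified_evaluate",
]


@dataclass
class KMCurve:
    """Product-limit estimate on an event-time grid."""

    times: np.ndarray
    survival: np.ndarray
    at_risk: np.ndarray
    median: float | None

    def survival_at(self, t: float) -> float:
        i = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if i < 0 else float(self.survival[i])


def logrank(
    groups: RiskScoreTable, survival: ClinicalTable
) -> tuple[float, float]:
    """Two-group log-rank test between high- and low-risk samples.

    Returns (chi-square statistic with 1 df, p-value). Tied event times use
    the standard hypergeometric variance.
    """
    hi = groups.samples_in(HIGH)
    lo = groups.samples_in(LOW)
    if not hi or not lo:
        raise ValueError("both risk groups must be non-empty")
    clin = survival.data
    missing = (set(hi) | set(lo)) - set(survival.samples)
    if missing:
        raise ValueError(f"samples without survival data: {sorted(missing)[:5]}")
    if survival.event.loc[hi + lo].sum() < 1:
        raise ValueError("no events observed in either group")
    res = logrank_test(
        clin.loc[hi, "time_months"], clin.loc[lo, "time_months"],
        event_observed_A=clin.loc[hi, "event"],
        event_observed_B=clin.loc[lo, "event"],
    )
    return float(res.test_statistic), float(res.p_value)


def km_curve(
    times: Sequence[float] | pd.Series, events: Sequence[int] | pd.Series
) -> KMCurve:
    """Kaplan-Meier curve; median = earliest time with S(t) <= 0.5 (or None)."""
    t = np.asarray(times, dtype=float)
    e = np.asarray(events, dtype=int)
    if t.size == 0:
        raise ValueError("no subjects")
    kmf = KaplanMeierFitter()
    kmf.fit(t, e)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)
    at_risk = kmf.event_table["at_risk"].reindex(
        kmf.survival_function_.index
    ).to_numpy(dtype=float)
    below = np.flatnonzero(surv <= 0.5)
    median = float(grid[below[0]]) if below.size else None
    return KMCurve(times=grid, survival=surv, at_risk=at_risk, median=median)


def multivariate_cox_backward(
    survival: ClinicalTable,
    covariate_cols: Sequence[str],
    p_stay: float = 0.05,
) -> pd.DataFrame:
    """Backward stepwise multivariate Cox PH on complete cases.

    Starting from all covariates, the covariate with the largest Wald p
    above ``p_stay`` is dropped and the model refit until every retained
    covariate has p <= ``p_stay``. Returns the summary of the retained
    covariates (columns ``coef, HR, ci_low, ci_high, p``); may be empty.
    Rows with any missing covariate are dropped with a logged count.
    """
    cols = list(covariate_cols)
    df = survival.data[["time_months", "event", *cols]].copy()
    n0 = len(df)
    df = df.dropna()
    if len(df) < n0:
        logger.warning(
            "complete-case analysis: dropped %d of %d subjects with "
            "missing covariates", n0 - len(df), n0,
        )
    if df["event"].sum() < 1:
        raise ValueError("no events among complete cases")

    retained = cols
    while retained:
        sub = df[["time_months", "event", *retained]]
        try:
            cph = CoxPHFitter()
            cph.fit(sub, duration_col="time_months", event_col="event")
        except Exception as exc:  # convergence/separation
            try:
                cph = CoxPHFitter(penalizer=0.1)
                cph.fit(sub, duration_col="time_months", event_col="event")
            except Exception:
                warnings.warn(
                    f"Cox fit failed ({exc}); dropping covariate "
                    f"{retained[-1]!r}"
                )
                retained = retained[:-1]
                continue
        pvals = cph.summary["p"]
        worst = pvals.idxmax()
        if pvals[worst] > p_stay:
            retained = [c for c in retained if c != worst]
            continue
        out = cph.summary
        return pd.DataFrame(
            {
                "coef": out["coef"],
                "HR": out["exp(coef)"],
                "ci_low": np.exp(out["coef lower 95%"]),
                "ci_high": np.exp(out["coef upper 95%"]),
                "p": out["p"],
            }
        )
    return pd.DataFrame(columns=["coef", "HR", "ci_low", "ci_high", "p"])


def _censoring_survival_left(
    times: np.ndarray, events: np.ndarray
) -> Callable[[np.ndarray], np.ndarray]:
    """Left-continuous KM estimate G(t-) of the censoring distribution."""
    kmf = KaplanMeierFitter()
    kmf.fit(times, 1 - events)
    grid = kmf.survival_function_.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.iloc[:, 0].to_numpy(dtype=float)

    def g_left(t: np.ndarray) -> np.ndarray:
        idx = np.searchsorted(grid, np.asarray(t, dtype=float), side="left") - 1
        out = np.where(idx < 0, 1.0, surv[np.clip(idx, 0, len(surv) - 1)])
        return out

    return g_left


def _ipcw_auc(
    scores: np.ndarray, times: np.ndarray, events: np.ndarray, horizon: float
) -> float:
    cases = (times <= horizon) & (events == 1)
    controls = times > horizon
    if not cases.any() or not controls.any():
        raise ValueError(
            f"no cases or no controls at horizon {horizon}"
        )
    g_left = _censoring_survival_left(times, events)
    g_case = g_left(times[cases])
    if (g_case <= 0).any():
        g_case = np.maximum(g_case, g_case[g_case > 0].min()
                            if (g_case > 0).any() else 1.0)
    w = 1.0 / g_case
    sc = scores[cases][:, None]
    so = scores[controls][None, :]
    conc = (sc > so).astype(float) + 0.5 * (sc == so)
    # Control weights 1/G(horizon) are constant and cancel in the ratio.
    num = (w[:, None] * conc).sum()
    den = w.sum() * controls.sum()
    return float(num / den)


def td_roc(
    scores: pd.Series | np.ndarray,
    survival: ClinicalTable,
    horizon: float,
) -> float:
    """Cumulative/dynamic AUC at ``horizon`` with IPCW case weights.

    Cases: event by the horizon; controls: still at risk past the horizon.
    With no censoring before the horizon this equals the Mann-Whitney
    statistic of scores, cases vs controls.
    """
    if isinstance(scores, pd.Series):
        scores = scores.reindex(survival.samples)
        if scores.isna().any():
            raise ValueError("scores missing for some clinical samples")
        scores = scores.to_numpy(dtype=float)
    else:
        scores = np.asarray(scores, dtype=float)
    t = survival.time.to_numpy(dtype=float)
    e = survival.event.to_numpy(dtype=int)
    if not (t.min() <= horizon <= t.max()):
        raise ValueError(
            f"horizon {horizon} outside observed time range "
            f"[{t.min()}, {t.max()}]"
        )
    return _ipcw_auc(scores, t, e, horizon)


def compare_auc(
    scores_a: pd.Series | np.ndarray,
    scores_b: pd.Series | np.ndarray,
    survival: ClinicalTable,
    horizon: float,
    n_boot: int = 500,
    seed: int | None = None,
) -> tuple[float, float]:
    """Paired test of two IPCW AUCs computed on the same samples.

    Bootstrap resampling of subjects yields the sampling distribution of the
    AUC difference; the p-value is a two-sided normal test of the observed
    difference against the bootstrap standard error.
    Returns (auc_a - auc_b, p).
    """
    def as_array(s):
        if isinstance(s, pd.Series):
            s = s.reindex(survival.samples).to_numpy(dtype=float)
        return np.asarray(s, dtype=float)

    a = as_array(scores_a)
    b = as_array(scores_b)
    t = survival.time.to_numpy(dtype=float)
    e = survival.event.to_numpy(dtype=int)
    delta = _ipcw_auc(a, t, e, horizon) - _ipcw_auc(b, t, e, horizon)
    rng = np.random.default_rng(seed)
    n = len(t)
    diffs = []
    for _ in range(n_boot):
        idx = rng.integers(n, size=n)
        try:
            d = (_ipcw_auc(a[idx], t[idx], e[idx], horizon)
                 - _ipcw_auc(b[idx], t[idx], e[idx], horizon))
        except ValueError:
            continue  # resample without cases or controls
        diffs.append(d)
    if len(diffs) < 2:
        raise ValueError("bootstrap produced too few valid resamples")
    se = float(np.std(diffs, ddof=1))
    if se == 0:
        return delta, 1.0 if delta == 0 else 0.0
    p = 2 * stats.norm.sf(abs(delta) / se)
    return float(delta), float(p)


def activity_correlation(
    activity: ActivityMatrix, members: Sequence[str] | None = None
) -> pd.DataFrame:
    """Pairwise Pearson correlation of member activity vectors.

    Zero-variance rows yield NaN entries, flagged with a warning.
    """
    ids = list(members) if members is not None else activity.subpathway_ids
    if len(ids) < 2:
        raise ValueError("need >= 2 members to correlate")
    sub = activity.data.loc[ids]
    sd = sub.std(axis=1, ddof=1)
    flat = list(sd.index[sd == 0])
    if flat:
        warnings.warn(f"zero-variance activity row(s): {flat}; entries NaN")
    corr = sub.T.corr(method="pearson")
    np.fill_diagonal(corr.values, 1.0)
    for fid in flat:
        corr.loc[fid, :] = np.nan
        corr.loc[:, fid] = np.nan
    return corr


def stratified_evaluate(
    predicate: Callable[[pd.DataFrame], pd.Series],
    groups: RiskScoreTable,
    survival: ClinicalTable,
) -> dict:
    """Log-rank + per-group KM on the subset selected by ``predicate``.

    The predicate maps the clinical frame to a boolean mask (e.g.
    ``lambda df: df["er_status"] == "positive"``).
    """
    mask = predicate(survival.data)
    samples = list(survival.data.index[np.asarray(mask, dtype=bool)])
    if not samples:
        raise ValueError("stratum is empty")
    clin = survival.subset(samples)
    sub_groups = RiskScoreTable(groups.data.loc[
        [s for s in samples if s in groups.data.index]
    ])
    chi2, p = logrank(sub_groups, clin)
    curves = {}
    for grp in (HIGH, LOW):
        members = [s for s in sub_groups.samples_in(grp)]
        curves[grp] = km_curve(
            clin.data.loc[members, "time_months"],
            clin.data.loc[members, "event"],
        )
    return {
        "n": len(samples),
        "logrank_chi2": chi2,
        "logrank_p": p,
        "km": curves,
        "median_survival": {g: curves[g].median for g in curves},
    }
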