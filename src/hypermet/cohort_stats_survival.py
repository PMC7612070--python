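"""Cohort statistics and expression-dichotomization survival analysis.

Small-cohort statistics follow the study's conventions: Pearson
correlation with a two-sided t-based p-value, two-sided Student t tests
(paired when baseline and follow-up of the same patients are compared),
and no multiple-testing correction by default — significant results are
exploratory.  The survival stage mirrors the large-cohort validation:
expression log-intensities are standardized to z-scores, dichotomized at
a percentile (default 85th, "overexpression" strictly above it), and the
two groups compared with Kaplan-Meier estimation and a log-rank test.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test as _ll_logrank
from scipy import stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "StatResult",
    "SurvivalRecord",
    "pearson_test",
    "t_test",
    "zscore_and_dichotomize",
    "km_estimate",
    "logrank_test",
    "correlation_matrix",
    "adjust_pvalues",
]


@dataclass(frozen=True)
class StatResult:
    """A test statistic with its two-sided p-value."""

    statistic: float
    p_value: float
    n: int
    df: float
    test_name: str
    paired_flag: bool = False

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_value <= 1.0:
            raise ValueError("p-value outside [0, 1]")
        if self.test_name == "pearson" and not -1.0 <= self.statistic <= 1.0:
            raise ValueError("correlation coefficient outside [-1, 1]")


@dataclass(frozen=True)
class SurvivalRecord:
    """One sample in the dichotomized survival analysis."""

    sample_id: str
    expression_z: float
    group: str  # "high" or "normal"
    time: float  # months
    event: bool

    def __post_init__(self) -> None:
        if self.time < 0:
            raise ValueError("time must be >= 0")
        if self.group not in ("high", "normal"):
            raise ValueError("group must be 'high' or 'normal'")


def pearson_test(x: np.ndarray, y: np.ndarray) -> StatResult:
    """Pearson correlation with a two-sided p from t = r sqrt((n-2)/(1-r^2))."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1 or x.size < 3:
        raise ValueError("need matching 1-D arrays with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("inputs must be finite")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("correlation undefined for zero-variance input")
    res = stats.pearsonr(x, y)
    return StatResult(statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=x.size,
                      df=x.size - 2, test_name="pearson")


def t_test(a: np.ndarray, b: np.ndarray, paired: bool = False) -> StatResult:
    """Two-sided Student t test; paired variant operates on differences."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.ndim != 1 or b.ndim != 1 or a.size < 2 or b.size < 2:
        raise ValueError("need 1-D samples with n >= 2 per group")
    if paired:
        if a.size != b.size:
            raise ValueError("paired test requires equal lengths")
        d = a - b
        if np.ptp(d) == 0:
            if d[0] != 0:  # constant nonzero shift: t = inf, test degenerate
                raise ValueError(
                    "degenerate paired test: zero-variance differences")
            return StatResult(statistic=0.0, p_value=1.0, n=a.size,
                              df=float(a.size - 1), test_name="t",
                              paired_flag=True)
        res = stats.ttest_rel(a, b)
        df = a.size - 1
        n = a.size
    else:
        if np.ptp(a) == 0 and np.ptp(b) == 0:
            raise ValueError("degenerate test: both groups constant")
        res = stats.ttest_ind(a, b)
        df = a.size + b.size - 2
        n = a.size + b.size
    return StatResult(statistic=float(res.statistic),
                      p_value=float(res.pvalue), n=n, df=float(df),
                      test_name="t", paired_flag=paired)


def zscore_and_dichotomize(expression: np.ndarray, percentile: float = 85.0,
                           sample_ids: list[str] | None = None,
                           times: np.ndarray | None = None,
                           events: np.ndarray | None = None,
                           ) -> pd.DataFrame:
    """Standardize log-intensities to z-scores and split at a percentile.

    z = (x - mean) / SD (sample SD, ddof=1).  The "high" group is strictly
    above the percentile of the z-scores (linear-interpolation percentile
    definition, numpy default).  Returns a table with columns sample_id,
    expression_z, group (and time/event when supplied).
    """
    x = np.asarray(expression, dtype=float)
    if x.ndim != 1 or x.size < 20:
        raise ValueError("need >= 20 samples for a stable percentile")
    sd = x.std(ddof=1)
    if sd < 1e-12 * max(1.0, abs(x.mean())):
        raise ValueError("constant expression: z-scores undefined")
    z = (x - x.mean()) / sd
    cut = np.percentile(z, percentile)
    group = np.where(z > cut, "high", "normal")
    df = pd.DataFrame({
        "sample_id": sample_ids if sample_ids is not None
        else [f"S{i + 1:05d}" for i in range(x.size)],
        "expression_z": z,
        "group": group,
    })
    if times is not None:
        df["time"] = np.asarray(times, dtype=float)
    if events is not None:
        df["event"] = np.asarray(events).astype(bool)
    return df


def km_estimate(times: np.ndarray, events: np.ndarray
                ) -> tuple[np.ndarray, np.ndarray]:
    """Product-limit (Kaplan-Meier) survival estimate.

    Returns ``(event_times, survival)`` with S(0) = 1 prepended; censored
    records reduce the risk set without stepping the curve.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events).astype(bool)
    if np.any(t < 0):
        raise ValueError("times must be >= 0")
    if t.shape != e.shape:
        raise ValueError("times and events must match")
    kmf = KaplanMeierFitter()
    kmf.fit(t, event_observed=e)
    sf = kmf.survival_function_
    return sf.index.to_numpy(dtype=float), sf.iloc[:, 0].to_numpy(dtype=float)


def logrank_test(times_a: np.ndarray, events_a: np.ndarray,
                 times_b: np.ndarray, events_b: np.ndarray) -> StatResult:
    """Two-group log-rank test (chi-square on observed vs expected events)."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    ea = np.asarray(events_a).astype(bool)
    eb = np.asarray(events_b).astype(bool)
    if np.any(ta < 0) or np.any(tb < 0):
        raise ValueError("times must be >= 0")
    if ea.sum() + eb.sum() == 0:
        raise ValueError("log-rank test requires at least one event")
    res = _ll_logrank(ta, tb, event_observed_A=ea, event_observed_B=eb)
    return StatResult(statistic=float(res.test_statistic),
                      p_value=float(res.p_value),
                      n=ta.size + tb.size, df=1.0, test_name="logrank")


def correlation_matrix(expression_table: pd.DataFrame,
                       gene_list: list[str]
                       ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Pairwise Pearson r and p matrices over the listed gene columns.

    Both matrices are symmetric; the r diagonal is 1 and the p diagonal 0.
    """
    if len(gene_list) < 2:
        raise ValueError("need >= 2 genes")
    missing = [g for g in gene_list if g not in expression_table.columns]
    if missing:
        raise KeyError(f"genes absent from table: {missing}")
    g = len(gene_list)
    r = np.eye(g)
    p = np.zeros((g, g))
    for i in range(g):
        for j in range(i + 1, g):
            res = pearson_test(expression_table[gene_list[i]].to_numpy(),
                               expression_table[gene_list[j]].to_numpy())
            r[i, j] = r[j, i] = res.statistic
            p[i, j] = p[j, i] = res.p_value
    return (pd.DataFrame(r, index=gene_list, columns=gene_list),
            pd.DataFrame(p, index=gene_list, columns=gene_list))


def adjust_pvalues(p_values: np.ndarray, method: str = "fdr_bh") -> np.ndarray:
    """Optional Benjamini-Hochberg adjustment (off by default everywhere)."""
    return multipletests(np.asarray(p_values, dtype=float), method=method)[1]
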