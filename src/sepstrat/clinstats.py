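"""Clinical comparison layer: nonparametric group tests, contingency tests,
and survival analysis.

Kruskal-Wallis and Pearson chi-squared come from scipy; Kaplan-Meier and
log-rank from lifelines. Dunn's post-hoc z statistics (pooled-rank mean
differences with tie-corrected variance) are computed directly since no
installed package provides them. Chi-squared uses no continuity correction
and no small-cell fallback by default (Fisher's exact test is available
behind a flag for 2x2 tables).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from lifelines import KaplanMeierFitter
from lifelines.statistics import logrank_test

from .de import bh_adjust

__all__ = [
    "kruskal_wallis",
    "dunn_posthoc",
    "chi_squared",
    "proportion_ratio",
    "km_estimate",
    "log_rank",
    "SurvivalCurve",
]


def kruskal_wallis(groups: list) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) and its chi-squared p-value."""
    groups = [np.asarray(g, dtype=float) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least 2 groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("groups must be nonempty")
    if sum(len(g) for g in groups) < 3:
        raise ValueError("need at least 3 observations in total")
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:  # all values identical: no evidence of difference
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def dunn_posthoc(groups: list, p_adjust: str = "none") -> pd.DataFrame:
    """Dunn's post-hoc pairwise comparisons after Kruskal-Wallis.

    z for groups a, b: (mean rank a - mean rank b) /
    sqrt((N(N+1)/12 - T) (1/n_a + 1/n_b)) with tie correction
    T = sum(t^3 - t) / (12 (N - 1)). Two-sided normal p-values, optionally
    BH-adjusted across the pairs.
    """
    if len(groups) < 3:
        raise ValueError("Dunn's test needs >= 3 groups (use a rank-sum test for 2)")
    if p_adjust not in {"none", "bh"}:
        raise ValueError(f"unknown p_adjust {p_adjust!r}")
    groups = [np.asarray(g, dtype=float) for g in groups]
    sizes = [len(g) for g in groups]
    if any(s == 0 for s in sizes):
        raise ValueError("groups must be nonempty")
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = stats.rankdata(pooled)
    bounds = np.cumsum([0] + sizes)
    mean_ranks = [ranks[bounds[i] : bounds[i + 1]].mean() for i in range(len(groups))]
    _, tie_counts = np.unique(pooled, return_counts=True)
    tie_term = np.sum(tie_counts**3 - tie_counts) / (12.0 * (n - 1))
    var_base = n * (n + 1) / 12.0 - tie_term
    rows = []
    for i, j in itertools.combinations(range(len(groups)), 2):
        se = np.sqrt(var_base * (1.0 / sizes[i] + 1.0 / sizes[j]))
        z = (mean_ranks[i] - mean_ranks[j]) / se
        rows.append({"group_a": i, "group_b": j, "z": float(z), "p": float(2 * stats.norm.sf(abs(z)))})
    table = pd.DataFrame(rows)
    table["p_adj"] = bh_adjust(table["p"].to_numpy()) if p_adjust == "bh" else table["p"]
    return table


def chi_squared(table, use_fisher: bool = False) -> tuple[float, int, float]:
    """Pearson chi-squared test of independence, no continuity correction.

    ``table`` is groups x outcomes with nonnegative integer cells. With
    ``use_fisher=True`` a 2x2 table is tested with Fisher's exact test
    instead (X2 reported as NaN).
    """
    t = np.asarray(table, dtype=float)
    if t.ndim != 2 or t.shape[0] < 2 or t.shape[1] < 2:
        raise ValueError("need a contingency table with >= 2 rows and >= 2 columns")
    if (t < 0).any():
        raise ValueError("cells must be nonnegative")
    if (t.sum(axis=0) == 0).any() or (t.sum(axis=1) == 0).any():
        raise ValueError("zero row or column marginal")
    if use_fisher:
        if t.shape != (2, 2):
            raise ValueError("Fisher's exact test requires a 2x2 table")
        _, p = stats.fisher_exact(t.astype(int))
        return float("nan"), 1, float(p)
    res = stats.chi2_contingency(t, correction=False)
    return float(res.statistic), int(res.dof), float(res.pvalue)


def proportion_ratio(
    positives_a, totals_a, positives_b, totals_b
) -> float:
    """Ratio of pooled proportions: (sum posA / sum totA) / (sum posB / sum totB).

    Returns inf when group B has no pooled positives.
    """
    pa, ta = np.sum(positives_a), np.sum(totals_a)
    pb, tb = np.sum(positives_b), np.sum(totals_b)
    if ta <= 0 or tb <= 0:
        raise ValueError("totals must be positive")
    if pb == 0:
        import warnings

        warnings.warn("no positives in group B; ratio is infinite")
        return float("inf")
    return float((pa / ta) / (pb / tb))


@dataclass
class SurvivalCurve:
    times: np.ndarray  # event times, ascending
    survival: np.ndarray  # S(t) just after each time
    at_risk: np.ndarray  # risk-set size just before each time
    censored_times: np.ndarray  # censoring marks

    def __post_init__(self) -> None:
        s = np.asarray(self.survival, dtype=float)
        if len(s) and (np.any(np.diff(s) > 1e-12) or s.min() < -1e-12 or s.max() > 1 + 1e-12):
            raise ValueError("survival curve must be nonincreasing within [0, 1]")

    def at(self, t: float) -> float:
        """S(t): survival probability at time t (right-continuous step)."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


def km_estimate(times, events) -> SurvivalCurve:
    """Kaplan-Meier product-limit estimator.

    ``events`` is 1 for an observed event, 0 for right censoring; censored
    subjects leave the risk set after their time.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events).astype(int)
    if (times < 0).any():
        raise ValueError("times must be nonnegative")
    if not set(np.unique(events)) <= {0, 1}:
        raise ValueError("events must be binary")
    kmf = KaplanMeierFitter()
    kmf.fit(times, event_observed=events)
    tbl = kmf.event_table
    event_rows = tbl[tbl["observed"] > 0]
    event_times = event_rows.index.to_numpy(dtype=float)
    surv = kmf.survival_function_.loc[event_times, "KM_estimate"].to_numpy()
    return SurvivalCurve(
        times=event_times,
        survival=surv,
        at_risk=event_rows["at_risk"].to_numpy(dtype=float),
        censored_times=np.sort(times[events == 0]),
    )


def log_rank(times1, events1, times2, events2) -> tuple[float, float]:
    """Two-group log-rank test: (chi-squared statistic with 1 df, p-value)."""
    t1, t2 = np.asarray(times1, dtype=float), np.asarray(times2, dtype=float)
    e1, e2 = np.asarray(events1).astype(int), np.asarray(events2).astype(int)
    if len(t1) == 0 or len(t2) == 0:
        raise ValueError("both groups must be nonempty")
    if e1.sum() + e2.sum() == 0:
        raise ValueError("log-rank test undefined: no events in either group")
    res = logrank_test(t1, t2, event_observed_A=e1, event_observed_B=e2)
    return float(res.test_statistic), float(res.p_value)
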