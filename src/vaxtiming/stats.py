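"""Survival-style statistics for age-at-vaccination analyses.

Age at vaccination is treated as a time-to-event outcome: a child
vaccinated at age *a* days contributes an event at *a*; a child not (yet)
vaccinated by the analysis horizon is right-censored there (administrative
censoring, default 365 days).  Coverage at age *t* is one minus the
product-limit (Kaplan-Meier) survival estimate, so coverage curves rise
toward the proportion ever vaccinated.

The estimators and tests here — product-limit curve, k-sample log-rank,
Mood's median test, Pearson chi-square — are implemented directly from
their defining formulas; only chi-square tail probabilities come from
scipy.  This keeps every arithmetic step of the audit inspectable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Optional, Sequence

import numpy as np
from scipy.stats import chi2 as _chi2

__all__ = [
    "AgeSample", "KMCurve", "TestResult",
    "km_curve", "logrank_test", "median_iqr", "round_half_up",
    "mood_median_test", "chisq_independence",
]


@dataclass(frozen=True)
class AgeSample:
    """One child's age (days) at an event or censoring."""

    age: float
    observed: bool = True
    group: Optional[str] = None

    def __post_init__(self):
        if self.age < 0:
            raise ValueError("age must be non-negative")


@dataclass(frozen=True)
class TestResult:
    statistic: float
    df: int
    p_value: float
    method: str


@dataclass(frozen=True)
class KMCurve:
    """Product-limit estimate, tabulated at the distinct event times."""

    times: np.ndarray      # strictly increasing event times
    at_risk: np.ndarray    # risk-set size just before each time
    events: np.ndarray     # events at each time
    survival: np.ndarray   # S(t) just after each time
    horizon: float

    @property
    def coverage(self) -> np.ndarray:
        return 1.0 - self.survival

    def survival_at(self, t: float) -> float:
        """Step-function value S(t); right-continuous."""
        idx = np.searchsorted(self.times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])

    def coverage_at(self, t: float) -> float:
        return 1.0 - self.survival_at(t)

    @property
    def median_time(self) -> Optional[float]:
        """Smallest event time with S(t) <= 0.5, or None if never reached."""
        below = np.nonzero(self.survival <= 0.5)[0]
        return float(self.times[below[0]]) if below.size else None


def _apply_horizon(samples: Iterable[AgeSample], horizon: float) -> tuple[np.ndarray, np.ndarray]:
    ages, observed = [], []
    for s in samples:
        if s.age > horizon:
            ages.append(horizon)
            observed.append(False)
        else:
            ages.append(s.age)
            observed.append(s.observed)
    return np.asarray(ages, dtype=float), np.asarray(observed, dtype=bool)


def km_curve(samples: Sequence[AgeSample], horizon: float = 365.0) -> KMCurve:
    """Kaplan-Meier product-limit estimator of age at vaccination.

    Events past the horizon are administratively censored at it.  Ties at a
    time are processed together; censorings at a time leave the risk set
    after the events at that time (the usual convention).
    """
    if len(samples) == 0:
        raise ValueError("km_curve needs at least one sample")
    ages, observed = _apply_horizon(samples, horizon)
    event_times = np.unique(ages[observed])
    n = len(ages)
    times, at_risk, events, survival = [], [], [], []
    s = 1.0
    for t in event_times:
        r = int(np.sum(ages >= t))
        d = int(np.sum((ages == t) & observed))
        s *= 1.0 - d / r
        times.append(t)
        at_risk.append(r)
        events.append(d)
        survival.append(s)
    return KMCurve(
        times=np.asarray(times, dtype=float),
        at_risk=np.asarray(at_risk, dtype=int),
        events=np.asarray(events, dtype=int),
        survival=np.asarray(survival, dtype=float),
        horizon=horizon,
    )


def logrank_test(groups: Sequence[Sequence[AgeSample]], horizon: float = np.inf) -> TestResult:
    """k-sample log-rank test comparing age-at-vaccination curves.

    At each distinct event time the observed events per group are compared
    with their expectation under the pooled hazard; the quadratic form of
    the (O - E) vector in the inverse hypergeometric covariance gives a
    chi-square statistic on k - 1 degrees of freedom.
    """
    k = len(groups)
    if k < 2:
        raise ValueError("logrank_test needs at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    ages_l, obs_l = [], []
    for g in groups:
        a, o = _apply_horizon(g, horizon)
        ages_l.append(a)
        obs_l.append(o)
    pooled_events = np.unique(np.concatenate([a[o] for a, o in zip(ages_l, obs_l)]))
    if pooled_events.size == 0:
        raise ValueError("no events in any group")

    oe = np.zeros(k)
    cov = np.zeros((k, k))
    for t in pooled_events:
        n_j = np.array([np.sum(a >= t) for a in ages_l], dtype=float)
        d_j = np.array([np.sum((a == t) & o) for a, o in zip(ages_l, obs_l)], dtype=float)
        n = n_j.sum()
        d = d_j.sum()
        if n <= 1:
            continue
        e_j = d * n_j / n
        oe += d_j - e_j
        frac = n_j / n
        hyper = d * (n - d) / (n - 1.0)
        cov += hyper * (np.diag(frac) - np.outer(frac, frac))

    v = cov[: k - 1, : k - 1]
    u = oe[: k - 1]
    stat = float(u @ np.linalg.pinv(v) @ u)
    df = k - 1
    p = float(_chi2.sf(stat, df))
    return TestResult(statistic=stat, df=df, p_value=p, method="log-rank")


def median_iqr(ages: Sequence[float]) -> tuple[float, float, float]:
    """(median, Q1, Q3) with linear interpolation between closest ranks."""
    arr = np.asarray(list(ages), dtype=float)
    if arr.size == 0:
        raise ValueError("median_iqr needs at least one value")
    med, q1, q3 = np.percentile(arr, [50, 25, 75], method="linear")
    return float(med), float(q1), float(q3)


def round_half_up(x: float, decimals: int = 0) -> float:
    """Round with ties away from zero at the given decimal (table output)."""
    factor = 10.0 ** decimals
    return float(np.floor(np.abs(x) * factor + 0.5) / factor * np.sign(x)) if x else 0.0


def _pearson_chi2(table: np.ndarray) -> tuple[float, int, np.ndarray]:
    row = table.sum(axis=1, keepdims=True)
    col = table.sum(axis=0, keepdims=True)
    expected = row @ col / table.sum()
    stat = float(((table - expected) ** 2 / expected).sum())
    df = (table.shape[0] - 1) * (table.shape[1] - 1)
    return stat, df, expected


def mood_median_test(groups: Sequence[Sequence[float]]) -> TestResult:
    """Mood's median test for equality of group medians.

    Pools all values, counts per group how many lie above the grand median
    versus at-or-below it, and applies the Pearson chi-square to the
    resulting 2 x k table.  Ties at the grand median count as "at or
    below".  If the pooled data are so tied that one side of the table is
    empty the test is degenerate and reported with p = 1.
    """
    if len(groups) < 2:
        raise ValueError("mood_median_test needs at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("every group must be non-empty")
    pooled = np.concatenate([np.asarray(list(g), dtype=float) for g in groups])
    grand = float(np.median(pooled))
    above = np.array([np.sum(np.asarray(list(g)) > grand) for g in groups], dtype=float)
    not_above = np.array([len(g) for g in groups], dtype=float) - above
    table = np.vstack([above, not_above])
    df = len(groups) - 1
    if table.sum(axis=1).min() == 0:
        return TestResult(statistic=0.0, df=df, p_value=1.0,
                          method="Mood's median (degenerate: all values tied)")
    stat, df, _ = _pearson_chi2(table)
    return TestResult(statistic=stat, df=df, p_value=float(_chi2.sf(stat, df)),
                      method="Mood's median")


def chisq_independence(table) -> TestResult:
    """Pearson chi-square test of independence on an r x c count table.

    No continuity correction.  Expected counts below 5 trigger a warning
    (the asymptotic reference may be poor) but not an error; a zero row or
    column margin is an error.
    """
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] < 2 or arr.shape[1] < 2:
        raise ValueError("table must be at least 2 x 2")
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    if arr.sum(axis=1).min() == 0 or arr.sum(axis=0).min() == 0:
        raise ValueError("zero row or column margin")
    stat, df, expected = _pearson_chi2(arr)
    if (expected < 5).any():
        warnings.warn("expected cell count below 5; chi-square approximation may be poor")
    return TestResult(statistic=stat, df=df, p_value=float(_chi2.sf(stat, df)),
                      method="Pearson chi-square")
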