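"""Kaplan-Meier estimation and two-group weighted log-rank tests.

Both the product-limit estimator and the tests are written out from their
defining formulas.  At each distinct pooled event time t_j with n_j subjects
at risk (n_1j in group 1) and d_j events (d_1j in group 1):

    O_1j − E_1j  with  E_1j = d_j n_1j / n_j
    V_j = d_j (n_1j/n_j) (1 − n_1j/n_j) (n_j − d_j) / (n_j − 1)

and the statistic is  [Σ_j w_j (O_1j − E_1j)]² / Σ_j w_j² V_j  referred to
chi-square with 1 df.  Weights: w_j = 1 gives the standard log-rank test;
w_j = n_j gives the Gehan-Breslow-Wilcoxon test, which up-weights early
event times (where most subjects are still at risk).

Conventions: censored subjects at time t are still at risk for events at t
(events precede censorings at tied times); the KM median is the smallest t
with S(t) ≤ 0.5 and is undefined (NaN) when S never reaches 0.5.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import ParameterError, SurvivalError

__all__ = ["KMCurve", "SurvTestResult", "km_fit", "weighted_logrank", "compare_by_label"]


@dataclass
class KMCurve:
    """Product-limit estimate on the grid of distinct event times."""

    times: np.ndarray  # distinct event times, ascending
    at_risk: np.ndarray  # n_j just before each event time
    events: np.ndarray  # d_j
    survival: np.ndarray  # S(t_j)
    median: float  # NaN when undefined
    n: int

    def step_function(self):
        """Return S as a right-continuous step function of t."""

        def S(t: float) -> float:
            idx = np.searchsorted(self.times, t, side="right") - 1
            return 1.0 if idx < 0 else float(self.survival[idx])

        return S


@dataclass
class SurvTestResult:
    """Two-group weighted log-rank test result (chi-square, 1 df)."""

    name: str  # "log-rank" or "gehan-breslow-wilcoxon"
    statistic: float
    p_value: float
    observed: dict = field(default_factory=dict)
    expected: dict = field(default_factory=dict)

    def summary(self) -> str:
        return (
            f"{self.name}: chi2 = {self.statistic:.4f}, p = {self.p_value:.4g} "
            f"(O/E group1 {self.observed.get(1, float('nan')):.0f}"
            f"/{self.expected.get(1, float('nan')):.2f})"
        )


def km_fit(times, events) -> KMCurve:
    """Kaplan-Meier product-limit estimate.

    ``times`` ≥ 0, ``events`` binary (1 = event, 0 = censored).  All-censored
    input yields a flat curve with undefined median.
    """
    t = np.asarray(times, dtype=float)
    e = np.asarray(events)
    if t.size == 0:
        raise ParameterError("km_fit needs ≥1 record")
    if (t < 0).any():
        raise ParameterError("negative survival times")
    if not np.isin(e, [0, 1]).all():
        raise ParameterError("events must be 0/1")
    order = np.argsort(t, kind="stable")
    t, e = t[order], e[order]
    event_times = np.unique(t[e == 1])
    n = t.size
    at_risk = np.empty(event_times.size)
    d = np.empty(event_times.size)
    for j, tj in enumerate(event_times):
        at_risk[j] = np.sum(t >= tj)  # censored at tj still at risk at tj
        d[j] = np.sum((t == tj) & (e == 1))
    with np.errstate(invalid="ignore"):
        surv = np.cumprod(1.0 - d / at_risk)
    below = np.nonzero(surv <= 0.5)[0]
    median = float(event_times[below[0]]) if below.size else float("nan")
    return KMCurve(
        times=event_times, at_risk=at_risk, events=d, survival=surv, median=median, n=int(n)
    )


def weighted_logrank(
    times_a, events_a, times_b, events_b, weight: str = "logrank"
) -> SurvTestResult:
    """Weighted log-rank test between two groups.

    ``weight="logrank"`` uses w_j = 1; ``weight="breslow"`` uses w_j = n_j
    (the Gehan-Breslow-Wilcoxon test).  Symmetric in group order.
    """
    if weight not in ("logrank", "breslow"):
        raise ParameterError(f"unknown weight {weight!r}")
    ta, ea = np.asarray(times_a, float), np.asarray(events_a)
    tb, eb = np.asarray(times_b, float), np.asarray(events_b)
    if ta.size == 0 or tb.size == 0:
        raise SurvivalError("both groups must be non-empty")
    if ea.sum() + eb.sum() == 0:
        raise SurvivalError("no events in either group")
    t = np.concatenate([ta, tb])
    e = np.concatenate([ea, eb]).astype(int)
    g = np.concatenate([np.ones(ta.size, int), np.full(tb.size, 2)])
    event_times = np.unique(t[e == 1])
    num = 0.0
    den = 0.0
    o1 = e1 = o2 = e2 = 0.0
    for tj in event_times:
        at = t >= tj
        nj = float(at.sum())
        n1j = float((at & (g == 1)).sum())
        dj = float(((t == tj) & (e == 1)).sum())
        d1j = float(((t == tj) & (e == 1) & (g == 1)).sum())
        e1j = dj * n1j / nj
        vj = 0.0
        if nj > 1:
            p1 = n1j / nj
            vj = dj * p1 * (1 - p1) * (nj - dj) / (nj - 1)
        wj = nj if weight == "breslow" else 1.0
        num += wj * (d1j - e1j)
        den += wj * wj * vj
        o1 += d1j
        e1 += e1j
        o2 += dj - d1j
        e2 += dj - e1j
    if den == 0:
        statistic, p = 0.0, 1.0
    else:
        statistic = num * num / den
        p = float(stats.chi2.sf(statistic, df=1))
    name = "gehan-breslow-wilcoxon" if weight == "breslow" else "log-rank"
    return SurvTestResult(
        name=name,
        statistic=float(statistic),
        p_value=p,
        observed={1: o1, 2: o2},
        expected={1: e1, 2: e2},
    )


def compare_by_label(
    samples: pd.DataFrame, label_col: str, endpoint: str = "os"
) -> dict:
    """KM curves, medians and both tests for a two-level grouping.

    ``endpoint`` selects the ``os_months``/``os_event`` or ``rfs_*`` columns.
    Samples with labels other than the two retained levels (e.g.
    "indeterminate") are dropped and counted.

    Returns a dict: ``groups`` (label → KMCurve), ``medians``, ``tests``
    (name → SurvTestResult), ``n_dropped``.
    """
    if endpoint not in ("os", "rfs"):
        raise ParameterError("endpoint must be 'os' or 'rfs'")
    tcol, ecol = f"{endpoint}_months", f"{endpoint}_event"
    for c in (tcol, ecol, label_col):
        if c not in samples.columns:
            raise ParameterError(f"sample table missing column {c!r}")
    from .signature import LABEL_TIE

    table = samples[[label_col, tcol, ecol]].dropna()
    table = table[table[label_col] != LABEL_TIE]
    levels = sorted(table[label_col].unique())
    n_dropped = len(samples) - len(table)
    if len(levels) != 2:
        raise SurvivalError(f"need exactly 2 label levels, got {levels}")
    ga = table[table[label_col] == levels[0]]
    gb = table[table[label_col] == levels[1]]
    curves = {
        levels[0]: km_fit(ga[tcol], ga[ecol]),
        levels[1]: km_fit(gb[tcol], gb[ecol]),
    }
    tests = {}
    for w in ("breslow", "logrank"):
        res = weighted_logrank(ga[tcol], ga[ecol], gb[tcol], gb[ecol], weight=w)
        tests[res.name] = res
    return {
        "groups": curves,
        "medians": {lv: curves[lv].median for lv in levels},
        "tests": tests,
        "n_dropped": int(n_dropped),
        "levels": levels,
    }
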