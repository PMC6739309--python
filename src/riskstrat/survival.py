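"""Kaplan-Meier product-limit estimation and the two-group log-rank test.

Ties are handled in the standard way: events sharing a time are aggregated
(d_j >= 1) and the log-rank variance at each distinct event time is the
hypergeometric d_j (n_j - d_j) n_1j n_2j / (n_j^2 (n_j - 1)). Subjects
censored at an event time count as at risk at that time (event before
censoring). The implementation exposes the observed/expected/variance
ledger; lifelines serves as an independent cross-check in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = ["KMCurve", "LogRankResult", "km_estimate", "logrank_test"]


@dataclass
class KMCurve:
    """Product-limit survival estimates over the distinct event times."""

    event_times: np.ndarray  # increasing, distinct times with >= 1 event
    survival: np.ndarray  # S(t) just after each event time
    at_risk: np.ndarray  # n at risk just before each event time
    events: np.ndarray  # deaths at each event time

    def survival_at(self, t: float) -> float:
        """Step-function evaluation of S(t); S(0) = 1."""
        idx = np.searchsorted(self.event_times, t, side="right") - 1
        return 1.0 if idx < 0 else float(self.survival[idx])


@dataclass
class LogRankResult:
    statistic: float  # chi-square, 1 df
    p: float
    observed: tuple[float, float]  # events per group
    expected: tuple[float, float]
    variance: float
    df: int = 1


def _validate(time, event):
    time = np.asarray(time, dtype=float)
    event = np.asarray(event, dtype=int)
    if time.shape != event.shape:
        raise ValueError("time and event must have equal length")
    if time.size and ((time < 0).any() or ~np.isfinite(time).all()):
        raise ValueError("times must be finite and >= 0")
    if not np.isin(event, (0, 1)).all():
        raise ValueError("event indicator must be 0/1")
    return time, event


def km_estimate(time, event) -> KMCurve:
    """Kaplan-Meier estimator for one group.

    Censored-only times reduce the at-risk count but add no step in S.
    """
    time, event = _validate(time, event)
    if time.size == 0:
        raise ValueError("need at least one subject")
    order = np.argsort(time, kind="stable")
    time, event = time[order], event[order]

    ev_times = np.unique(time[event == 1])
    n = time.size
    at_risk = np.empty(ev_times.size)
    deaths = np.empty(ev_times.size, dtype=int)
    for j, t in enumerate(ev_times):
        at_risk[j] = np.sum(time >= t)
        deaths[j] = np.sum((time == t) & (event == 1))
    surv = np.cumprod(1.0 - deaths / at_risk)
    return KMCurve(
        event_times=ev_times,
        survival=surv,
        at_risk=at_risk,
        events=deaths,
    )


def logrank_test(time, event, group) -> LogRankResult:
    """Two-group log-rank test with aggregated ties.

    At each distinct event time the expected group-1 events and the
    hypergeometric variance are accumulated; the statistic is
    (O_1 - E_1)^2 / V on 1 df, invariant under group-label swap.
    """
    time, event = _validate(time, event)
    group = np.asarray(group)
    labels = np.unique(group)
    if labels.size != 2:
        raise ValueError(f"need exactly two groups, got {labels.size}")
    g1 = group == labels[0]
    if event.sum() == 0:
        raise ValueError("no events observed")

    ev_times = np.unique(time[event == 1])
    O1 = E1 = V = 0.0
    O2 = E2 = 0.0
    for t in ev_times:
        at = time >= t
        n_j = at.sum()
        n1 = (at & g1).sum()
        n2 = n_j - n1
        dead = (time == t) & (event == 1)
        d_j = dead.sum()
        d1 = (dead & g1).sum()
        O1 += d1
        O2 += d_j - d1
        E1 += d_j * n1 / n_j
        E2 += d_j * n2 / n_j
        if n_j > 1:
            V += d_j * (n_j - d_j) * n1 * n2 / (n_j**2 * (n_j - 1))
    if V <= 0:
        raise ValueError("degenerate design: zero log-rank variance")
    statistic = (O1 - E1) ** 2 / V
    p = float(stats.chi2.sf(statistic, df=1))
    return LogRankResult(
        statistic=float(statistic),
        p=max(p, np.finfo(float).tiny),
        observed=(float(O1), float(O2)),
        expected=(float(E1), float(E2)),
        variance=float(V),
    )
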