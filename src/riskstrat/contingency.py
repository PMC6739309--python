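"""Exact 2x2 contingency statistics.

Cells follow the epidemiological layout for an exposure (biomarker >= tau)
crossed with a binary event (death)::

            event   no event
  exposed     a        b        (row total a+b)
  unexposed   c        d        (row total c+d)

Fisher's exact test uses the two-sided minimum-likelihood rule on the
conditional hypergeometric distribution; the risk ratio carries a Katz
log-scale confidence interval, the odds ratio a Woolf interval, and tables
with a zero event cell receive the Haldane-Anscombe +0.5 correction (flagged,
never silent) so that threshold scans can traverse extreme cut-offs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import stats

__all__ = [
    "ConfusionMatrix2x2",
    "RatioEstimate",
    "from_groups",
    "fisher_exact_two_sided",
    "pearson_chi_square",
    "risk_ratio_ci",
    "odds_ratio_ci",
]

# relative tolerance when comparing hypergeometric point probabilities in the
# two-sided summation; absorbs float rounding (the exact rule uses equality)
_TIE_RTOL = 1e-7


@dataclass(frozen=True)
class ConfusionMatrix2x2:
    """Counts for exposure x outcome; marginals are derived, never stored."""

    a: int  # exposed & event
    b: int  # exposed & no event
    c: int  # unexposed & event
    d: int  # unexposed & no event

    def __post_init__(self) -> None:
        for name in "abcd":
            v = getattr(self, name)
            if v < 0 or v != int(v):
                raise ValueError(f"cell {name} must be a nonnegative integer, got {v}")

    @property
    def n(self) -> int:
        return self.a + self.b + self.c + self.d

    @property
    def n_exposed(self) -> int:
        return self.a + self.b

    @property
    def n_unexposed(self) -> int:
        return self.c + self.d

    @property
    def n_events(self) -> int:
        return self.a + self.c

    @property
    def risk_exposed(self) -> float:
        return self.a / self.n_exposed

    @property
    def risk_unexposed(self) -> float:
        return self.c / self.n_unexposed

    def has_zero_margin(self) -> bool:
        return 0 in (self.n_exposed, self.n_unexposed, self.n_events,
                     self.b + self.d)

    def cells(self) -> tuple[int, int, int, int]:
        return (self.a, self.b, self.c, self.d)


@dataclass(frozen=True)
class RatioEstimate:
    """A ratio (RR or OR) with its log-scale confidence interval."""

    estimate: float
    ci_low: float
    ci_high: float
    level: float = 0.95
    corrected: bool = False


def from_groups(dichotomized, outcomes=None) -> ConfusionMatrix2x2:
    """Cross-tabulate a :class:`~riskstrat.cohort.DichotomizedCohort`.

    Outcomes are taken from the grouped rows' ``outcome`` column unless an
    explicit per-subject mapping (subject_id -> 0/1) is given.
    """

    def _events(frame):
        if outcomes is None:
            col = frame["outcome"]
        else:
            col = frame["subject_id"].map(outcomes)
        if col.isna().any():
            missing = frame.loc[col.isna(), "subject_id"].iloc[0]
            raise ValueError(f"missing outcome for subject {missing!r}")
        return col.astype(int)

    hi = _events(dichotomized.high)
    lo = _events(dichotomized.low)
    return ConfusionMatrix2x2(
        a=int(hi.sum()),
        b=int((1 - hi).sum()),
        c=int(lo.sum()),
        d=int((1 - lo).sum()),
    )


def fisher_exact_two_sided(m: ConfusionMatrix2x2) -> float:
    """Two-sided Fisher exact p-value by the minimum-likelihood rule.

    With margins fixed, the p-value is the sum of hypergeometric point
    probabilities not exceeding that of the observed table (up to a 1e-7
    relative tolerance for float ties). A zero margin makes the table
    degenerate and returns p = 1.
    """
    if m.n < 1:
        raise ValueError("empty table")
    if m.has_zero_margin():
        return 1.0
    n, r, k = m.n, m.n_exposed, m.n_events
    support = np.arange(max(0, r + k - n), min(r, k) + 1)
    probs = stats.hypergeom.pmf(support, n, k, r)
    p_obs = probs[support == m.a][0]
    p = float(probs[probs <= p_obs * (1.0 + _TIE_RTOL)].sum())
    return min(p, 1.0)


def pearson_chi_square(
    m: ConfusionMatrix2x2, yates: bool = False
) -> tuple[float, float]:
    """Pearson chi-square statistic and p-value (1 df) for a 2x2 table.

    ``yates`` applies the continuity correction |O-E| - 0.5. The default is
    uncorrected. Raises on a zero margin (an expected count would be 0).
    """
    if m.has_zero_margin():
        raise ValueError("degenerate table: zero margin")
    obs = np.array(m.cells(), dtype=float).reshape(2, 2)
    rows = obs.sum(axis=1, keepdims=True)
    cols = obs.sum(axis=0, keepdims=True)
    expected = rows @ cols / m.n
    diff = np.abs(obs - expected)
    if yates:
        diff = np.maximum(diff - 0.5, 0.0)
    statistic = float((diff**2 / expected).sum())
    p = float(stats.chi2.sf(statistic, df=1))
    return statistic, max(p, np.finfo(float).tiny)


def _corrected_cells(m: ConfusionMatrix2x2, zero_cells) -> tuple[tuple, bool]:
    if any(c == 0 for c in zero_cells):
        return tuple(x + 0.5 for x in m.cells()), True
    return m.cells(), False


def risk_ratio_ci(m: ConfusionMatrix2x2, level: float = 0.95) -> RatioEstimate:
    """Risk ratio with Katz log-method CI.

    RR = [a/(a+b)] / [c/(c+d)]; CI = exp(ln RR +/- z * sqrt(1/a - 1/(a+b)
    + 1/c - 1/(c+d))). If a or c is zero, all four cells get +0.5
    (Haldane-Anscombe) and the estimate is flagged as corrected.
    """
    if m.n_exposed == 0 or m.n_unexposed == 0:
        raise ValueError("risk ratio undefined: an exposure row is empty")
    (a, b, c, d), corrected = _corrected_cells(m, (m.a, m.c))
    n1, n0 = a + b, c + d
    rr = (a / n1) / (c / n0)
    se = np.sqrt(1 / a - 1 / n1 + 1 / c - 1 / n0)
    z = stats.norm.ppf(0.5 + level / 2)
    return RatioEstimate(
        estimate=float(rr),
        ci_low=float(rr * np.exp(-z * se)),
        ci_high=float(rr * np.exp(z * se)),
        level=level,
        corrected=corrected,
    )


def odds_ratio_ci(m: ConfusionMatrix2x2, level: float = 0.95) -> RatioEstimate:
    """Odds ratio ad/bc with Woolf log CI; +0.5 correction on any zero cell."""
    if m.n_exposed == 0 or m.n_unexposed == 0:
        raise ValueError("odds ratio undefined: an exposure row is empty")
    (a, b, c, d), corrected = _corrected_cells(m, m.cells())
    orr = (a * d) / (b * c)
    se = np.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    z = stats.norm.ppf(0.5 + level / 2)
    return RatioEstimate(
        estimate=float(orr),
        ci_low=float(orr * np.exp(-z * se)),
        ci_high=float(orr * np.exp(z * se)),
        level=level,
        corrected=corrected,
    )
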