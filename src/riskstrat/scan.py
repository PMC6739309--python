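"""Exhaustive threshold scan for optimal biomarker cut-point discovery.

Every distinct observed biomarker value whose ">= tau" split leaves both
groups at or above a size floor is a candidate cut-off. Each candidate gets
a 2x2 confusion matrix against the binary outcome, a two-sided Fisher exact
p-value, a Pearson chi-square p-value and a risk ratio with 95% CI. The best
cut-off minimizes the raw Fisher p among non-degenerate records (ties broken
by larger |ln RR|, then smaller tau). Multiplicity adjustment (Bonferroni or
Holm) is reported alongside but never used for selection, making the
optimism of the scan explicit.
"""

from __future__ import annotations

import json
from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .cohort import CohortTable, dichotomize_by_threshold
from .contingency import (
    ConfusionMatrix2x2,
    RatioEstimate,
    fisher_exact_two_sided,
    from_groups,
    pearson_chi_square,
    risk_ratio_ci,
)

__all__ = [
    "ScanConfig",
    "ThresholdRecord",
    "ScanLedger",
    "candidate_thresholds",
    "scan_thresholds",
    "select_best_threshold",
    "adjust_ledger_pvalues",
]


@dataclass(frozen=True)
class ScanConfig:
    min_group_size: int = 5
    adjust: str = "none"  # "bonferroni" | "holm" | "none"
    level: float = 0.95

    def __post_init__(self) -> None:
        if self.min_group_size < 1:
            raise ValueError("min_group_size must be >= 1")
        if self.adjust not in ("bonferroni", "holm", "none"):
            raise ValueError(f"unknown adjustment method: {self.adjust!r}")


@dataclass
class ThresholdRecord:
    tau: float
    matrix: ConfusionMatrix2x2
    fisher_p: float
    chi2_p: float
    rr: RatioEstimate | None
    group_sizes: tuple[int, int]  # (|high|, |low|)
    degenerate: bool
    adjusted_p: float | None = None

    def to_dict(self) -> dict:
        a, b, c, d = self.matrix.cells()
        return {
            "tau": self.tau,
            "a": a,
            "b": b,
            "c": c,
            "d": d,
            "fisher_p": self.fisher_p,
            "chi2_p": self.chi2_p,
            "rr": self.rr.estimate if self.rr else None,
            "ci_low": self.rr.ci_low if self.rr else None,
            "ci_high": self.rr.ci_high if self.rr else None,
            "rr_corrected": self.rr.corrected if self.rr else None,
            "adjusted_p": self.adjusted_p,
            "degenerate": self.degenerate,
        }


@dataclass
class ScanLedger:
    biomarker: str
    records: list[ThresholdRecord]
    config: ScanConfig
    n_missing: int = 0
    best: ThresholdRecord | None = None

    def non_degenerate(self) -> list[ThresholdRecord]:
        return [r for r in self.records if not r.degenerate]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame([r.to_dict() for r in self.records])

    def to_json(self, path=None) -> str:
        payload = {
            "biomarker": self.biomarker,
            "config": {
                "min_group_size": self.config.min_group_size,
                "adjust": self.config.adjust,
                "level": self.config.level,
            },
            "n_missing": self.n_missing,
            "records": [r.to_dict() for r in self.records],
            "best": self.best.to_dict() if self.best else None,
            "selection": "min raw fisher_p; ties by |ln RR| then smaller tau",
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    def to_tsv(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def candidate_thresholds(values, min_group_size: int = 5) -> np.ndarray:
    """Sorted unique observed values whose split respects the group floor."""
    arr = np.asarray(pd.Series(values).dropna(), dtype=float)
    uniq = np.unique(arr)
    if uniq.size < 2:
        raise ValueError("need at least 2 distinct non-missing values")
    n = arr.size
    out = []
    for tau in uniq:
        n_high = int((arr >= tau).sum())
        if n_high >= min_group_size and (n - n_high) >= min_group_size:
            out.append(tau)
    return np.asarray(out)


def scan_thresholds(
    cohort: CohortTable,
    biomarker: str,
    config: ScanConfig | None = None,
) -> ScanLedger:
    """Build the full per-threshold ledger and select the best cut-off."""
    config = config or ScanConfig()
    values = cohort.biomarker_values(biomarker)
    present = values.notna()
    outcomes = cohort.outcomes()[present]
    if outcomes.isna().any():
        raise ValueError("outcome missing for some subjects with biomarker data")
    if outcomes.nunique() < 2:
        raise ValueError("degenerate outcome: all subjects share one outcome")

    taus = candidate_thresholds(values, config.min_group_size)
    records = []
    for tau in taus:
        dich = dichotomize_by_threshold(cohort, biomarker, float(tau))
        m = from_groups(dich)
        degenerate = m.has_zero_margin()
        fisher_p = fisher_exact_two_sided(m)
        if degenerate:
            chi2_p = 1.0
            rr = None
        else:
            _, chi2_p = pearson_chi_square(m)
            rr = risk_ratio_ci(m, level=config.level)
        records.append(
            ThresholdRecord(
                tau=float(tau),
                matrix=m,
                fisher_p=fisher_p,
                chi2_p=chi2_p,
                rr=rr,
                group_sizes=(dich.n_high, dich.n_low),
                degenerate=degenerate,
            )
        )
    ledger = ScanLedger(
        biomarker=biomarker,
        records=records,
        config=config,
        n_missing=int((~present).sum()),
    )
    ledger = adjust_ledger_pvalues(ledger, config.adjust)
    if ledger.non_degenerate():
        ledger.best = select_best_threshold(ledger)
    return ledger


def select_best_threshold(ledger: ScanLedger) -> ThresholdRecord:
    """Record minimizing raw Fisher p among non-degenerate records.

    Ties broken by larger |ln RR|, then by smaller tau.
    """
    candidates = ledger.non_degenerate()
    if not candidates:
        raise ValueError("no non-degenerate threshold records to select from")

    def key(rec: ThresholdRecord):
        lnrr = abs(np.log(rec.rr.estimate)) if rec.rr else 0.0
        return (rec.fisher_p, -lnrr, rec.tau)

    return min(candidates, key=key)


def adjust_ledger_pvalues(ledger: ScanLedger, method: str) -> ScanLedger:
    """Fill adjusted_p over the non-degenerate records (in place, returned)."""
    if method not in ("bonferroni", "holm", "none"):
        raise ValueError(f"unknown adjustment method: {method!r}")
    live = ledger.non_degenerate()
    if method == "none":
        for rec in live:
            rec.adjusted_p = rec.fisher_p
        return ledger
    if live:
        raw = [r.fisher_p for r in live]
        _, adj, _, _ = multipletests(raw, method=method)
        for rec, p in zip(live, adj):
            rec.adjusted_p = float(p)
    return ledger
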