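"""Cohort data model, CSV/TSV I/O, and dichotomization at a threshold.

A cohort is one row per subject: a unique subject id, named biomarker
concentrations (missing values allowed), a binary outcome (1 = died), and
optional right-censored survival columns (``time`` in days, ``event``
indicator). Units are metadata only; no conversion is attempted.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "CohortTable",
    "DichotomizedCohort",
    "BiomarkerSummary",
    "SchemaError",
    "read_cohort_table",
    "write_cohort_table",
    "dichotomize_by_threshold",
    "summarize_biomarker",
]


class SchemaError(ValueError):
    """Raised when an input table does not match the declared schema."""


_RESERVED = ("subject_id", "outcome", "time", "event")


@dataclass
class CohortTable:
    """Validated per-subject cohort records.

    Parameters
    ----------
    data
        DataFrame with columns ``subject_id``, ``outcome``, optional
        ``time``/``event``, and one float column per biomarker.
    biomarkers
        Names of the biomarker columns, in order.
    units
        Optional unit label per biomarker (metadata only).
    """

    data: pd.DataFrame
    biomarkers: list[str]
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self._validate()

    def _validate(self) -> None:
        df = self.data
        for col in ("subject_id", "outcome"):
            if col not in df.columns:
                raise SchemaError(f"missing mandatory column: {col!r}")
        if df["subject_id"].duplicated().any():
            dup = df.loc[df["subject_id"].duplicated(), "subject_id"].iloc[0]
            raise SchemaError(f"duplicate subject_id: {dup!r}")
        out = df["outcome"].dropna()
        if not out.isin([0, 1]).all():
            raise SchemaError("outcome must be binary (0/1)")
        if ("time" in df.columns) != ("event" in df.columns):
            raise SchemaError("time and event columns must be present together")
        if "time" in df.columns:
            t = df["time"].dropna()
            if (t < 0).any() or not np.isfinite(t).all():
                raise SchemaError("survival times must be finite and >= 0")
            ev = df["event"].dropna()
            if not ev.isin([0, 1]).all():
                raise SchemaError("event indicator must be binary (0/1)")
        for name in self.biomarkers:
            if name not in df.columns:
                raise SchemaError(f"biomarker column missing: {name!r}")
            vals = df[name].dropna().to_numpy(dtype=float)
            if vals.size and (~np.isfinite(vals) | (vals < 0)).any():
                raise SchemaError(
                    f"biomarker {name!r} has non-finite or negative values"
                )

    @property
    def n(self) -> int:
        return len(self.data)

    @property
    def has_survival(self) -> bool:
        return "time" in self.data.columns

    def biomarker_values(self, name: str) -> pd.Series:
        if name not in self.biomarkers:
            raise KeyError(f"unknown biomarker: {name!r}")
        return self.data[name]

    def outcomes(self) -> pd.Series:
        return self.data["outcome"]

    def equals(self, other: "CohortTable") -> bool:
        if self.biomarkers != other.biomarkers:
            return False
        a = self.data.reset_index(drop=True)
        b = other.data.reset_index(drop=True)
        return a.equals(b)


@dataclass
class DichotomizedCohort:
    """Partition of a cohort at a biomarker threshold.

    ``high`` holds the rows with value >= ``threshold`` (ties go high,
    matching the ">= cut-off" group definition), ``low`` the rows below it;
    subjects with a missing biomarker value are excluded and counted in
    ``n_missing``.
    """

    biomarker_name: str
    threshold: float
    high: pd.DataFrame
    low: pd.DataFrame
    n_missing: int

    @property
    def n_high(self) -> int:
        return len(self.high)

    @property
    def n_low(self) -> int:
        return len(self.low)


@dataclass
class BiomarkerSummary:
    median: float
    q1: float
    q3: float
    iqr: float
    n: int
    n_missing: int


def read_cohort_table(path, schema: dict | None = None) -> CohortTable:
    """Read a CSV/TSV cohort file into a validated :class:`CohortTable`.

    ``schema`` maps logical names to file columns::

        {"subject_id": "ID", "outcome": "death", "time": "fu_days",
         "event": "dead", "biomarkers": {"eNAPRT": "naprt_ng_ml"}}

    Without a schema, ``subject_id`` and ``outcome`` columns are expected
    verbatim and every other column is treated as a biomarker (except
    ``time``/``event``). Empty cells are recorded as missing, never as zero.
    """
    path = str(path)
    sep = "\t" if path.endswith((".tsv", ".txt")) else ","
    raw = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    raw = raw.replace({"": np.nan, "NA": np.nan, "NaN": np.nan, "nan": np.nan})

    if schema is None:
        mapping = {c: c for c in _RESERVED if c in raw.columns}
        bio_map = {
            c: c for c in raw.columns if c not in _RESERVED
        }
    else:
        mapping = {k: schema[k] for k in _RESERVED if k in schema}
        bio_map = dict(schema.get("biomarkers", {}))

    for logical in ("subject_id", "outcome"):
        col = mapping.get(logical, logical)
        if col not in raw.columns:
            raise SchemaError(f"missing mandatory column: {col!r}")

    df = pd.DataFrame()
    df["subject_id"] = raw[mapping.get("subject_id", "subject_id")]
    df["outcome"] = _numeric(raw, mapping.get("outcome", "outcome"))
    for logical in ("time", "event"):
        col = mapping.get(logical)
        if col is not None:
            if col not in raw.columns:
                raise SchemaError(f"missing column: {col!r}")
            df[logical] = _numeric(raw, col)

    biomarkers = []
    for name, col in bio_map.items():
        if col not in raw.columns:
            raise SchemaError(f"biomarker column missing: {col!r}")
        df[name] = _numeric(raw, col)
        biomarkers.append(name)

    return CohortTable(data=df, biomarkers=biomarkers)


def _numeric(raw: pd.DataFrame, col: str) -> pd.Series:
    try:
        return pd.to_numeric(raw[col])
    except (ValueError, TypeError):
        bad = pd.to_numeric(raw[col], errors="coerce")
        row = int(np.nonzero(bad.isna().to_numpy() & raw[col].notna().to_numpy())[0][0])
        raise SchemaError(
            f"non-numeric value in column {col!r} at data row {row + 1}: "
            f"{raw[col].iloc[row]!r}"
        ) from None


def write_cohort_table(cohort: CohortTable, path) -> None:
    """Write a cohort as CSV with header; missing values as empty cells."""
    cohort.data.to_csv(path, index=False)


def dichotomize_by_threshold(
    cohort: CohortTable, biomarker: str, threshold: float
) -> DichotomizedCohort:
    """Split a cohort at ``threshold`` on ``biomarker`` (ties go high)."""
    values = cohort.biomarker_values(biomarker)
    present = values.notna()
    if not present.any():
        raise ValueError(f"all values of {biomarker!r} are missing")
    df = cohort.data[present]
    vals = values[present]
    hi_mask = vals >= threshold
    return DichotomizedCohort(
        biomarker_name=biomarker,
        threshold=float(threshold),
        high=df[hi_mask],
        low=df[~hi_mask],
        n_missing=int((~present).sum()),
    )


def summarize_biomarker(values) -> BiomarkerSummary:
    """Median (midpoint convention) and IQR (linear-interpolated quartiles)."""
    arr = np.asarray(pd.Series(values), dtype=float)
    missing = int(np.isnan(arr).sum())
    arr = arr[~np.isnan(arr)]
    if arr.size == 0:
        raise ValueError("no non-missing values to summarize")
    q1, med, q3 = np.percentile(arr, [25, 50, 75])
    return BiomarkerSummary(
        median=float(med),
        q1=float(q1),
        q3=float(q3),
        iqr=float(q3 - q1),
        n=int(arr.size),
        n_missing=missing,
    )
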