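"""Reading, validating, filtering, and partitioning cohort tables.

This module is pure plumbing: it loads delimited-text assessment tables into
typed records, applies the registry exclusion rules in a fixed order, extracts
the longitudinal subset, and performs the reproducible training/validation
split.  No statistics live here.

File dialect: CSV, one row per patient x timepoint, ISO-8601 dates, empty
string for a missing cell.  Records missing any of the nine clustering
symptoms are excluded (never imputed) by :func:`apply_exclusions`.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .schema import (
    BOUNDED_RANGES,
    DEMOGRAPHICS,
    GH_MENTAL,
    ID_COLUMNS,
    PAIN_MEASURES,
    SYMPTOMS,
)

NUMERIC_COLUMNS: tuple[str, ...] = SYMPTOMS + PAIN_MEASURES + (GH_MENTAL, "age")


class SchemaError(ValueError):
    """A mandatory column is absent from the input file."""


@dataclass
class CohortTable:
    """An ordered collection of assessment records plus a filter log."""

    data: pd.DataFrame
    provenance: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.data)

    def log(self, message: str) -> None:
        self.provenance.append(message)

    def copy(self) -> "CohortTable":
        return CohortTable(self.data.copy(), list(self.provenance))


@dataclass
class ExclusionReport:
    """Counts of records removed per rule, in application order."""

    initial: int
    noncompleted: int
    missing_symptoms: int
    duplicates: int
    underage: int
    retained: int

    def __post_init__(self) -> None:
        removed = (
            self.noncompleted + self.missing_symptoms + self.duplicates + self.underage
        )
        if self.initial != self.retained + removed:
            raise ValueError("exclusion report does not reconcile")

    def to_json(self, path: str | Path | None = None) -> str:
        text = json.dumps(self.__dict__, indent=2)
        if path is not None:
            Path(path).write_text(text)
        return text


@dataclass
class SplitSpec:
    """Patient-id membership of the training/validation/longitudinal partitions."""

    training: list[str]
    validation: list[str]
    longitudinal: list[str]
    fraction: float
    seed: int

    def __post_init__(self) -> None:
        train, valid, longi = map(set, (self.training, self.validation, self.longitudinal))
        if train & valid or longi & (train | valid):
            raise ValueError("split partitions overlap")


def load_cohort(path: str | Path, schema: dict[str, str] | None = None) -> CohortTable:
    """Load a delimited assessment table into a typed cohort.

    Parameters
    ----------
    path
        CSV file with one row per patient x timepoint.
    schema
        Optional mapping from file column names to canonical names
        (e.g. ``{"PROMIS_Fatigue_T": "fatigue"}``).

    Unparseable numeric cells and out-of-range bounded measures become
    missing and are logged in the table's provenance.  Missing mandatory
    columns raise :class:`SchemaError` naming them.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    if schema:
        raw = raw.rename(columns=schema)

    required = list(ID_COLUMNS) + list(SYMPTOMS)
    missing_cols = [c for c in required if c not in raw.columns]
    if missing_cols:
        raise SchemaError(f"missing mandatory columns: {', '.join(missing_cols)}")

    cohort = CohortTable(raw, [f"loaded {len(raw)} records from {path}"])
    df = cohort.data
    df.replace("", np.nan, inplace=True)

    for col in NUMERIC_COLUMNS:
        if col not in df.columns:
            continue
        parsed = pd.to_numeric(df[col], errors="coerce")
        bad = parsed.isna() & df[col].notna()
        if bad.any():
            cohort.log(f"{col}: {int(bad.sum())} unparseable cells set to missing")
        df[col] = parsed

    for col, (lo, hi) in BOUNDED_RANGES.items():
        if col not in df.columns:
            continue
        out = df[col].notna() & ((df[col] < lo) | (df[col] > hi))
        if out.any():
            cohort.log(
                f"{col}: {int(out.sum())} values outside [{lo:g}, {hi:g}] "
                "flagged invalid and set to missing"
            )
            df.loc[out, col] = np.nan

    if "assessment_date" in df.columns:
        df["assessment_date"] = pd.to_datetime(df["assessment_date"], format="ISO8601")
    return cohort


def write_cohort(cohort: CohortTable | pd.DataFrame, path: str | Path) -> None:
    """Write a cohort in the same CSV dialect :func:`load_cohort` reads."""
    df = cohort.data if isinstance(cohort, CohortTable) else cohort
    df = df.copy()
    if "assessment_date" in df.columns:
        df["assessment_date"] = pd.to_datetime(df["assessment_date"]).dt.strftime(
            "%Y-%m-%d"
        )
    df.to_csv(path, index=False, na_rep="")


def apply_exclusions(
    cohort: CohortTable, min_age: float = 18
) -> tuple[CohortTable, ExclusionReport]:
    """Apply the registry exclusion rules in their fixed order.

    Order: (1) noncompleted or test records, (2) missing any of the nine
    clustering symptoms, (3) duplicated patient x timepoint (first kept),
    (4) age below ``min_age``.  A record failing several rules is counted
    once, under the earliest rule.
    """
    df = cohort.data
    initial = len(df)

    keep = pd.Series(True, index=df.index)
    if "completed" in df.columns:
        completed = df["completed"].astype(str).str.lower().isin(
            {"1", "true", "yes", "y", "t", "1.0"}
        )
        keep &= completed
    if "record_status" in df.columns:
        keep &= df["record_status"].astype(str).str.lower() != "test"
    n_noncompleted = int((~keep).sum())
    df = df[keep]

    complete = df[list(SYMPTOMS)].notna().all(axis=1)
    n_missing = int((~complete).sum())
    df = df[complete]

    dup = df.duplicated(subset=list(ID_COLUMNS), keep="first")
    n_dup = int(dup.sum())
    df = df[~dup]

    if "age" in df.columns:
        underage = df["age"].notna() & (df["age"] < min_age)
    else:
        underage = pd.Series(False, index=df.index)
    n_underage = int(underage.sum())
    df = df[~underage]

    report = ExclusionReport(
        initial=initial,
        noncompleted=n_noncompleted,
        missing_symptoms=n_missing,
        duplicates=n_dup,
        underage=n_underage,
        retained=len(df),
    )
    out = CohortTable(df.reset_index(drop=True), list(cohort.provenance))
    out.log(
        "exclusions: removed "
        f"{n_noncompleted} noncompleted/test, {n_missing} missing symptoms, "
        f"{n_dup} duplicates, {n_underage} underage; retained {len(df)}"
    )
    return out, report


def extract_longitudinal(
    cohort: CohortTable, window_days: tuple[int, int] = (90, 365)
) -> CohortTable:
    """Extract patients with a baseline and a qualifying follow-up.

    A follow-up qualifies when its gap from baseline lies within the closed
    ``window_days`` interval and the nine clustering symptoms are complete at
    both timepoints.  When several follow-ups qualify, the earliest is kept.
    Returns the baseline + chosen follow-up rows for each qualifying patient.
    """
    lo, hi = window_days
    df = cohort.data
    if "assessment_date" not in df.columns:
        raise ValueError("longitudinal extraction requires assessment dates")
    dates = pd.to_datetime(df["assessment_date"])

    complete = df[list(SYMPTOMS)].notna().all(axis=1)
    kept_idx: list = []
    for _, grp in df.groupby("patient_id", sort=False):
        base = grp[(grp["timepoint"] == "baseline") & complete.loc[grp.index]]
        if base.empty:
            continue
        b = base.index[0]
        fol = grp[(grp["timepoint"] == "followup") & complete.loc[grp.index]]
        if fol.empty:
            continue
        gaps = (dates.loc[fol.index] - dates.loc[b]).dt.days
        ok = gaps[(gaps >= lo) & (gaps <= hi)]
        if ok.empty:
            continue
        kept_idx.extend([b, ok.idxmin()])

    out = CohortTable(df.loc[kept_idx].reset_index(drop=True), list(cohort.provenance))
    out.log(
        f"longitudinal: {len(kept_idx) // 2} patients with follow-up "
        f"in [{lo}, {hi}] days"
    )
    return out


def split_train_validation(
    cohort: CohortTable, fraction: float = 0.75, seed: int = 0
) -> SplitSpec:
    """Randomly split patients into training and validation partitions.

    ``|training| = round(fraction * n)``; reproducible under ``seed``.
    Longitudinal patients must already have been removed from the pool; pass
    their ids separately via :class:`SplitSpec` if needed.
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError(f"fraction must lie in (0, 1), got {fraction}")
    ids = list(dict.fromkeys(cohort.data["patient_id"]))
    rng = np.random.default_rng(seed)
    order = rng.permutation(len(ids))
    n_train = round(fraction * len(ids))
    training = [ids[i] for i in sorted(order[:n_train])]
    validation = [ids[i] for i in sorted(order[n_train:])]
    return SplitSpec(training, validation, [], fraction, seed)


def subset_by_ids(cohort: CohortTable, ids: list[str]) -> CohortTable:
    """Rows belonging to the given patient ids, in original order."""
    mask = cohort.data["patient_id"].isin(set(ids))
    out = CohortTable(cohort.data[mask].reset_index(drop=True), list(cohort.provenance))
    out.log(f"subset: {int(mask.sum())} records for {len(ids)} patients")
    return out
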