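"""Cohort CSV reading/writing and DataFrame conversion.

The cohort CSV schema is one header row with the columns of
:data:`metsdx.records.CSV_COLUMNS` (booleans as 0/1, '.' decimals, optional
fields empty). Lines starting with '#' at the top of the file are provenance
comments (seed, spec hash) and are ignored on read.
"""

from __future__ import annotations

from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from pydantic import ValidationError

from .records import CSV_COLUMNS, DRUG_FLAGS, SubjectRecord


class SchemaError(ValueError):
    """The cohort CSV violates the expected schema."""


def frame_to_records(frame: pd.DataFrame) -> list[SubjectRecord]:
    """Validate a cohort DataFrame row by row into SubjectRecords.

    Raises :class:`SchemaError` naming the first offending row (1-based data
    row number) and field.
    """
    missing = [c for c in CSV_COLUMNS if c not in frame.columns and c != "fm_kg"]
    if missing:
        raise SchemaError(f"cohort table is missing required columns: {missing}")

    records = []
    for i, (_, row) in enumerate(frame.iterrows(), start=1):
        kwargs: dict = {"subject_id": str(row["subject_id"])}
        for col in CSV_COLUMNS[1:]:
            if col not in frame.columns:
                continue
            value = row[col]
            if pd.isna(value):
                continue
            kwargs[col] = bool(int(value)) if col in DRUG_FLAGS else float(value)
        try:
            records.append(SubjectRecord(**kwargs))
        except (ValidationError, ValueError) as exc:
            raise SchemaError(f"row {i}: {exc}") from exc
    if not records:
        raise SchemaError("cohort table contains no data rows")
    return records


def records_to_frame(records: Iterable[SubjectRecord]) -> pd.DataFrame:
    """Cohort DataFrame in canonical column order (drug flags as 0/1)."""
    rows = []
    for r in records:
        row = {col: getattr(r, col) for col in CSV_COLUMNS}
        for flag in DRUG_FLAGS:
            row[flag] = int(row[flag])
        rows.append(row)
    return pd.DataFrame(rows, columns=CSV_COLUMNS)


def read_cohort_csv(path: str | Path) -> list[SubjectRecord]:
    """Read and validate a cohort CSV ('#' comment lines permitted at top)."""
    frame = pd.read_csv(path, comment="#")
    return frame_to_records(frame)


def write_cohort_csv(
    records: Sequence[SubjectRecord],
    path: str | Path,
    header_comments: Optional[Sequence[str]] = None,
) -> None:
    """Write a cohort CSV, optionally preceded by '#' provenance comments."""
    frame = records_to_frame(records)
    with open(path, "w", encoding="utf-8", newline="") as fh:
        for line in header_comments or ():
            fh.write(f"# {line}\n")
        frame.to_csv(fh, index=False)
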