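"""Cohort CSV and JSON report readers/writers.

Cohort files are plain UTF-8 CSV with header
``animal_id,body_weight_kg,lung_weight_g,method`` and '.' as the decimal
separator.  Extra columns are tolerated (with a warning); malformed or
non-positive rows are rejected with the offending row number.
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .cohort import Method, PigRecord

__all__ = ["read_cohort", "write_cohort", "write_report", "read_report"]

logger = logging.getLogger(__name__)

COHORT_COLUMNS = ["animal_id", "body_weight_kg", "lung_weight_g", "method"]


def read_cohort(path) -> list[PigRecord]:
    """Read pig records from a cohort CSV; errors name the offending row."""
    df = pd.read_csv(path)
    missing = [c for c in COHORT_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    extra = [c for c in df.columns if c not in COHORT_COLUMNS]
    if extra:
        logger.warning("%s: ignoring extra columns %s", path, extra)
    records = []
    for row_num, row in enumerate(df.itertuples(index=False), start=2):
        try:
            records.append(
                PigRecord(
                    animal_id=str(row.animal_id),
                    body_weight=float(row.body_weight_kg),
                    lung_weight=float(row.lung_weight_g),
                    method=Method(str(row.method)),
                )
            )
        except (TypeError, ValueError) as exc:
            raise ValueError(f"{path}, row {row_num}: {exc}") from exc
    return records


def write_cohort(records: Iterable[PigRecord], path) -> None:
    """Write pig records to a cohort CSV (schema above)."""
    records = list(records)
    df = pd.DataFrame(
        {
            "animal_id": [r.animal_id for r in records],
            "body_weight_kg": [r.body_weight for r in records],
            "lung_weight_g": [r.lung_weight for r in records],
            "method": [r.method.value for r in records],
        }
    )
    df.to_csv(path, index=False)


def write_report(report: dict, path) -> None:
    """Write a machine-readable JSON report (round-trips with read_report)."""
    Path(path).write_text(json.dumps(report, indent=2, sort_keys=True) + "\n")


def read_report(path) -> dict:
    return json.loads(Path(path).read_text())
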