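"""CSV sample-table I/O.

The exchange format is a UTF-8 CSV with a header row and "." as decimal
separator.  Required columns: ``sample_id``, ``sflt1_pg_ml``,
``free_plgf_pg_ml``.  Optional: ``group``, ``timepoint`` (antepartum /
postpartum, default antepartum), ``day_postpartum``, ``ga_weeks``,
``total_plgf_pg_ml``.  Empty cells are treated as absent values; unknown
columns are preserved and passed through untouched.  All concentrations are
pg/mL; molar conversion is internal to the package.
"""

from __future__ import annotations

import math
import os
import tempfile
from pathlib import Path
from typing import List, Optional, Sequence, Union

import pandas as pd

from ._exceptions import PlgfBindError, SchemaError
from .binding import BiomarkerSample

__all__ = ["REQUIRED_COLUMNS", "OPTIONAL_COLUMNS", "read_samples", "write_samples",
           "samples_to_frame", "frame_to_samples", "atomic_write_csv"]

REQUIRED_COLUMNS = ("sample_id", "sflt1_pg_ml", "free_plgf_pg_ml")
OPTIONAL_COLUMNS = ("group", "timepoint", "day_postpartum", "ga_weeks", "total_plgf_pg_ml")

_NUMERIC = ("sflt1_pg_ml", "free_plgf_pg_ml", "total_plgf_pg_ml", "ga_weeks", "day_postpartum")


def _cell(row, col):
    if col not in row.index:
        return None
    v = row[col]
    if v is None or (isinstance(v, float) and math.isnan(v)):
        return None
    if isinstance(v, str) and v.strip() == "":
        return None
    return v


def frame_to_samples(df: pd.DataFrame) -> List[BiomarkerSample]:
    """Validate a sample-table DataFrame and build :class:`BiomarkerSample` objects.

    Raises :class:`SchemaError` listing every offending column or row (with
    1-based data row numbers) rather than stopping at the first problem.
    """
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"missing required column(s): {', '.join(missing)}")
    errors: list[str] = []
    samples: list[BiomarkerSample] = []
    for pos, (_, row) in enumerate(df.iterrows(), start=1):
        try:
            numeric = {}
            for col in _NUMERIC:
                raw = _cell(row, col)
                if raw is None:
                    numeric[col] = None
                    continue
                try:
                    numeric[col] = float(raw)
                except (TypeError, ValueError):
                    raise SchemaError(f"column {col!r}: cannot parse {raw!r} as a number")
                if numeric[col] < 0:
                    raise SchemaError(f"column {col!r}: negative value {numeric[col]}")
            for col in ("sflt1_pg_ml", "free_plgf_pg_ml"):
                if numeric[col] is None:
                    raise SchemaError(f"column {col!r}: value required")
            sid = _cell(row, "sample_id")
            if sid is None:
                raise SchemaError("column 'sample_id': value required")
            timepoint = _cell(row, "timepoint") or "antepartum"
            day = numeric["day_postpartum"]
            samples.append(
                BiomarkerSample(
                    sample_id=str(sid),
                    group=_cell(row, "group"),
                    timepoint=str(timepoint),
                    day_postpartum=int(day) if day is not None else None,
                    ga_weeks=numeric["ga_weeks"],
                    sflt1=numeric["sflt1_pg_ml"],
                    free_plgf=numeric["free_plgf_pg_ml"],
                    total_plgf=numeric["total_plgf_pg_ml"],
                )
            )
        except PlgfBindError as exc:
            errors.append(f"row {pos}: {exc}")
    if errors:
        raise SchemaError("invalid rows:\n" + "\n".join(errors))
    return samples


def read_samples(path: Union[str, Path]) -> List[BiomarkerSample]:
    """Read and validate a sample CSV."""
    df = pd.read_csv(path, dtype={"sample_id": str})
    return frame_to_samples(df)


def samples_to_frame(samples: Sequence[BiomarkerSample]) -> pd.DataFrame:
    """Tidy DataFrame form of a sample collection (pg/mL columns)."""
    return pd.DataFrame(
        {
            "sample_id": [s.sample_id for s in samples],
            "group": [s.group for s in samples],
            "timepoint": [s.timepoint for s in samples],
            "day_postpartum": [s.day_postpartum for s in samples],
            "ga_weeks": [s.ga_weeks for s in samples],
            "sflt1_pg_ml": [s.sflt1 for s in samples],
            "free_plgf_pg_ml": [s.free_plgf for s in samples],
            "total_plgf_pg_ml": [s.total_plgf for s in samples],
        }
    )


def atomic_write_csv(df: pd.DataFrame, path: Union[str, Path]) -> None:
    """Write a CSV via a temp file + rename so no partial output survives errors."""
    path = Path(path)
    fd, tmp = tempfile.mkstemp(dir=path.parent or Path("."), suffix=".tmp")
    try:
        with os.fdopen(fd, "w", encoding="utf-8", newline="") as fh:
            df.to_csv(fh, index=False)
        os.replace(tmp, path)
    except BaseException:
        if os.path.exists(tmp):
            os.unlink(tmp)
        raise


def write_samples(samples: Sequence[BiomarkerSample], path: Union[str, Path]) -> None:
    """Write samples to the standard CSV schema (atomic)."""
    atomic_write_csv(samples_to_frame(samples), path)
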