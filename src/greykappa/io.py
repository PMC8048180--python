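"""Reading and writing counts tables and results files.

The on-disk table format is a header-less CSV of q rows of q comma-
separated non-negative integers, rater A on rows and rater B on columns.
"""

from __future__ import annotations

import csv
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import TableParseError
from .measures import ContingencyTable


def read_table(path) -> ContingencyTable:
    """Parse a counts CSV into a :class:`ContingencyTable`.

    Raises :class:`~greykappa.errors.TableParseError` naming the offending
    row for empty, non-square, non-integer or negative input.
    """
    path = Path(path)
    rows: list[list[int]] = []
    with path.open(newline="") as fh:
        for lineno, record in enumerate(csv.reader(fh), start=1):
            record = [cell.strip() for cell in record]
            if not any(record):
                continue
            parsed = []
            for cell in record:
                try:
                    value = int(cell)
                except ValueError:
                    raise TableParseError(
                        f"{path}:{lineno}: non-integer cell {cell!r}"
                    ) from None
                if value < 0:
                    raise TableParseError(f"{path}:{lineno}: negative count {value}")
                parsed.append(value)
            rows.append(parsed)
    if not rows:
        raise TableParseError(f"{path}: empty table file")
    q = len(rows)
    for lineno, row in enumerate(rows, start=1):
        if len(row) != q:
            raise TableParseError(
                f"{path}:{lineno}: row has {len(row)} cells, expected {q} (square table)"
            )
    return ContingencyTable(np.array(rows, dtype=np.int64))


def write_table(table: ContingencyTable, path) -> None:
    """Write a counts table as a header-less CSV (lossless round-trip)."""
    path = Path(path)
    with path.open("w", newline="") as fh:
        writer = csv.writer(fh)
        for row in table.counts:
            writer.writerow([int(v) for v in row])


def write_results(results, path, fmt: str | None = None) -> None:
    """Write a results table (DataFrame or list of dicts) as CSV or JSON.

    ``fmt`` defaults from the path suffix; JSON uses record orientation so
    scenario metadata and seeds stay attached to every row.
    """
    path = Path(path)
    if fmt is None:
        fmt = "json" if path.suffix.lower() == ".json" else "csv"
    df = results if isinstance(results, pd.DataFrame) else pd.DataFrame(results)
    if fmt == "csv":
        df.to_csv(path, index=False)
    elif fmt == "json":
        path.write_text(json.dumps(df.to_dict(orient="records"), indent=2))
    else:
        raise ValueError(f"unknown results format {fmt!r}")
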