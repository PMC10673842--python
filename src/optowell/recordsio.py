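"""CSV logging of measurement records.

One CSV per signal (OD raw, OD adjusted, fluorescence): rows are
measurement epochs, the first column is ``time_h`` and the remaining 96
columns are wells A1..H12 row-major.  Missing values (e.g. a saturated well
or a channel not measured at that epoch) are written as the explicit marker
``NA`` and survive a round trip as NaN.  Files are written incrementally,
one row per epoch, so a crashed run keeps everything measured so far.
"""

from __future__ import annotations

import csv
from pathlib import Path

import numpy as np
import pandas as pd

from .wells import WELLS

_HEADER = ["time_h", *WELLS]
_NA = "NA"


def write_records(frame: pd.DataFrame, path: str | Path) -> None:
    """Write a wide per-signal table (columns time_h, A1..H12) to CSV."""
    cols = list(frame.columns)
    if cols != _HEADER:
        raise ValueError("expected columns time_h, A1..H12 row-major")
    frame.to_csv(path, index=False, na_rep=_NA)


def read_records(path: str | Path) -> pd.DataFrame:
    """Read a per-signal CSV back; inverse of write_records for finite and
    NA values alike."""
    try:
        frame = pd.read_csv(path, na_values=[_NA], keep_default_na=False)
    except pd.errors.ParserError as exc:
        raise ValueError(f"{path}: malformed records file: {exc}") from exc
    if list(frame.columns) != _HEADER:
        raise ValueError(f"{path}: expected columns time_h, A1..H12")
    n_fields = len(_HEADER)
    with open(path, newline="") as fh:
        for lineno, row in enumerate(csv.reader(fh), start=1):
            if len(row) != n_fields:
                raise ValueError(
                    f"{path}:{lineno}: expected {n_fields} fields, "
                    f"got {len(row)}")
    return frame


def append_epoch(path: str | Path, row: dict) -> None:
    """Append one epoch's row, creating the file with a header first."""
    path = Path(path)
    new = not path.exists()
    with open(path, "a", newline="") as fh:
        writer = csv.writer(fh)
        if new:
            writer.writerow(_HEADER)
        writer.writerow(
            [_NA if (isinstance(v, float) and np.isnan(v)) else repr(float(v))
             for v in (row[c] for c in _HEADER)])
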