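"""Reader/writer for the OpenSim STO/MOT whitespace time-series dialect.

Files carry a small ``key=value`` header terminated by ``endheader``, a
tab-separated column-name row whose first column is ``time`` (strictly
increasing), and one row per sample.  Values are written with 17
significant digits so a write/read round trip is exact.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd


class StoParseError(ValueError):
    """Malformed STO/MOT file; message includes the offending line number."""


def read_sto(path) -> pd.DataFrame:
    """Read an STO/MOT file into a DataFrame (``df.attrs`` keeps the header)."""
    path = Path(path)
    header = {}
    with open(path) as fh:
        lines = fh.read().splitlines()
    end = None
    for i, line in enumerate(lines):
        if line.strip() == "endheader":
            end = i
            break
        if "=" in line:
            key, _, val = line.partition("=")
            header[key.strip()] = val.strip()
        elif line.strip():
            header.setdefault("name", line.strip())
    if end is None:
        raise StoParseError(f"{path}: no 'endheader' line found")
    if end + 1 >= len(lines):
        raise StoParseError(f"{path}: line {end + 2}: missing column header row")
    columns = lines[end + 1].split("\t")
    if not columns or columns[0] != "time":
        raise StoParseError(
            f"{path}: line {end + 2}: first column must be 'time'")
    rows = []
    for ln, line in enumerate(lines[end + 2:], start=end + 3):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(columns):
            raise StoParseError(
                f"{path}: line {ln}: expected {len(columns)} columns, "
                f"got {len(parts)}")
        try:
            rows.append([float(p) for p in parts])
        except ValueError:
            raise StoParseError(f"{path}: line {ln}: non-numeric value") from None
    df = pd.DataFrame(rows, columns=columns)
    t = df["time"].to_numpy()
    if np.any(np.diff(t) <= 0):
        bad = int(np.argmax(np.diff(t) <= 0))
        raise StoParseError(
            f"{path}: line {end + 3 + bad + 1}: time column not strictly "
            "increasing")
    df.attrs["header"] = header
    df.attrs["in_degrees"] = header.get("inDegrees", "no").lower() == "yes"
    return df


def write_sto(table: pd.DataFrame, path, *, name: str | None = None,
              in_degrees: bool = False) -> None:
    """Write a DataFrame (first column ``time``) as an STO file."""
    path = Path(path)
    cols = list(table.columns)
    if not cols or cols[0] != "time":
        raise ValueError("first column must be 'time'")
    t = np.asarray(table["time"], dtype=float)
    if np.any(np.diff(t) <= 0):
        raise ValueError("time column must be strictly increasing")
    with open(path, "w") as fh:
        fh.write(f"{name or path.stem}\n")
        fh.write("version=1\n")
        fh.write(f"nRows={len(table)}\n")
        fh.write(f"nColumns={len(cols)}\n")
        fh.write(f"inDegrees={'yes' if in_degrees else 'no'}\n")
        fh.write("endheader\n")
        fh.write("\t".join(cols) + "\n")
        arr = table.to_numpy(dtype=float)
        for row in arr:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")
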