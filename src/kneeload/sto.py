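"""Reader/writer for the tab-delimited STO/MOT time-series dialect.

The format is a plain-text header (``nRows``/``nColumns``/``inDegrees``
key-value lines terminated by ``endheader``), one line of column labels with
``time`` first, then a numeric matrix.  Values are written with 17
significant digits so a write -> read round trip is bit-exact.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np


class StoFormatError(ValueError):
    """Malformed STO/MOT file; the message cites the offending line."""


@dataclass
class StoTable:
    name: str
    labels: list[str]          # column labels, "time" first
    data: np.ndarray           # (nRows, nColumns)
    in_degrees: bool = False
    version: int = 1
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2 or self.data.shape[1] != len(self.labels):
            raise StoFormatError(
                f"table {self.name!r}: data shape {self.data.shape} does not "
                f"match {len(self.labels)} labels"
            )
        if self.labels[0] != "time":
            raise StoFormatError("first column label must be 'time'")
        t = self.data[:, 0]
        if t.size > 1 and np.any(np.diff(t) <= 0):
            raise StoFormatError("time column must be strictly increasing")

    @property
    def time(self) -> np.ndarray:
        return self.data[:, 0]

    def column(self, label: str) -> np.ndarray:
        return self.data[:, self.labels.index(label)]


def read_sto(path: str | Path, to_radians: bool = True) -> StoTable:
    """Parse an STO/MOT file.

    With ``to_radians`` (default) the data of a file declaring
    ``inDegrees=yes`` are converted to radians on load (time column
    excluded) and the returned table is marked ``in_degrees=False``.
    """
    path = Path(path)
    lines = path.read_text().splitlines()
    meta: dict[str, str] = {}
    name = path.stem
    header_end = None
    for i, line in enumerate(lines):
        s = line.strip()
        if s == "endheader":
            header_end = i
            break
        if "=" in s:
            k, _, v = s.partition("=")
            meta[k.strip()] = v.strip()
        elif s:
            name = s
    if header_end is None:
        raise StoFormatError(f"{path}: missing 'endheader'")
    try:
        n_rows = int(meta["nRows"])
        n_cols = int(meta["nColumns"])
    except KeyError as e:
        raise StoFormatError(f"{path}: header missing {e}") from None
    in_degrees = meta.get("inDegrees", "no").lower() == "yes"
    labels = lines[header_end + 1].split("\t")
    labels = [s.strip() for s in labels if s.strip()]
    if len(labels) != n_cols:
        raise StoFormatError(
            f"{path}: line {header_end + 2}: {len(labels)} labels, header "
            f"declares nColumns={n_cols}"
        )
    rows = []
    for j, line in enumerate(lines[header_end + 2:], start=header_end + 3):
        if not line.strip():
            continue
        vals = line.split()
        if len(vals) != n_cols:
            raise StoFormatError(
                f"{path}: line {j}: {len(vals)} values, expected {n_cols}"
            )
        rows.append([float(v) for v in vals])
    if len(rows) != n_rows:
        raise StoFormatError(
            f"{path}: line {header_end + 2}: found {len(rows)} data rows, "
            f"header declares nRows={n_rows}"
        )
    data = np.array(rows, dtype=float)
    if in_degrees and to_radians:
        data[:, 1:] = np.deg2rad(data[:, 1:])
        in_degrees = False
    version = int(meta.get("version", 1))
    return StoTable(name=name, labels=labels, data=data,
                    in_degrees=in_degrees, version=version, meta=meta)


def write_sto(table: StoTable, path: str | Path) -> None:
    """Write a table in the STO dialect with 17-significant-digit numerics."""
    path = Path(path)
    n_rows, n_cols = table.data.shape
    with open(path, "w") as fh:
        fh.write(f"{table.name}\n")
        fh.write(f"version={table.version}\n")
        fh.write(f"nRows={n_rows}\n")
        fh.write(f"nColumns={n_cols}\n")
        fh.write(f"inDegrees={'yes' if table.in_degrees else 'no'}\n")
        fh.write("endheader\n")
        fh.write("\t".join(table.labels) + "\n")
        for row in table.data:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")
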