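"""Fluorescent peak tables: the interchange format of the pipeline.

A :class:`PeakTable` is one sample's fragment-analysis result: peaks keyed
by dye channel with fractional sizes (bp, against the size standard) and
heights (RFU).  Tables are read and written as plain CSV with the header
``sample_id,dye,size_bp,height_rfu``; the writer formats numbers with fixed
precision so that a seeded simulation reproduces byte-identical files.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

CSV_COLUMNS = ["sample_id", "dye", "size_bp", "height_rfu"]


@dataclass(frozen=True)
class Peak:
    dye: str
    size: float  # bp
    height: float  # RFU


@dataclass
class PeakTable:
    sample_id: str
    peaks: list[Peak]
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.peaks = sorted(self.peaks, key=lambda p: (p.dye, p.size))

    def channel(self, dye: str) -> list[Peak]:
        return [p for p in self.peaks if p.dye == dye]

    def max_height(self) -> float:
        return max((p.height for p in self.peaks), default=0.0)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(self.sample_id, p.dye, p.size, p.height) for p in self.peaks],
            columns=CSV_COLUMNS,
        )

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            writer = csv.writer(fh)
            writer.writerow(CSV_COLUMNS)
            for p in self.peaks:
                writer.writerow([self.sample_id, p.dye, f"{p.size:.2f}", f"{p.height:.2f}"])


def read_peak_tables(path: str | Path) -> list[PeakTable]:
    """Read one CSV file into one table per distinct sample_id.

    Malformed rows raise a ValueError naming the file and line number.
    """
    path = Path(path)
    groups: dict[str, list[Peak]] = {}
    with open(path, newline="") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != CSV_COLUMNS:
            raise ValueError(f"{path}:1: expected header {','.join(CSV_COLUMNS)}")
        for lineno, row in enumerate(reader, start=2):
            if not row or all(not c.strip() for c in row):
                continue
            if len(row) != 4:
                raise ValueError(f"{path}:{lineno}: expected 4 columns, got {len(row)}")
            sample_id, dye, size_s, height_s = (c.strip() for c in row)
            try:
                size = float(size_s)
                height = float(height_s)
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: non-numeric size/height") from exc
            if height < 0:
                raise ValueError(f"{path}:{lineno}: negative height {height}")
            groups.setdefault(sample_id, []).append(Peak(dye=dye, size=size, height=height))
    return [PeakTable(sample_id=sid, peaks=pks) for sid, pks in groups.items()]


def read_peak_table(path: str | Path) -> PeakTable:
    """Read a CSV expected to hold exactly one sample."""
    tables = read_peak_tables(path)
    if len(tables) != 1:
        raise ValueError(f"{path}: expected exactly one sample, found {len(tables)}")
    return tables[0]
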