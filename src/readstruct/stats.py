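"""Aggregation of structure strings into a ranked frequency table.

Counting is exact multiset counting over the structure strings of all
reads (single-end) or pairs (paired-end; one pair = one unit).  The rate
floor is purely a display device: rows below it are hidden from the
summary and rolled into a residual line, but counts and totals are never
altered, so shown rates plus the residual always sum to one.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

__all__ = ["StructureRow", "StructureTable", "FlooredTable", "aggregate", "apply_rate_floor"]

DEFAULT_RATE_FLOOR = 0.001


@dataclass(frozen=True)
class StructureRow:
    structure: str
    count: int
    rate: float


@dataclass(frozen=True)
class StructureTable:
    """Ranked structure-frequency table.

    Rows are sorted by count descending, ties broken lexicographically by
    structure string so reports are reproducible.
    """

    rows: tuple[StructureRow, ...]
    total_reads: int

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "structure": [r.structure for r in self.rows],
                "count": [r.count for r in self.rows],
                "rate": [r.rate for r in self.rows],
            }
        )


@dataclass(frozen=True)
class FlooredTable:
    """Display view of a :class:`StructureTable` under a rate floor.

    ``shown`` keeps every row whose rate reaches the floor; the residual
    fields report how many rows were hidden and their cumulative rate.
    The underlying table is unchanged.
    """

    shown: tuple[StructureRow, ...]
    hidden_count: int
    hidden_rate: float
    rate_floor: float
    total_reads: int


def aggregate(structures: Iterable[str]) -> StructureTable:
    """Count structure strings exactly; rate = count / total."""
    counts = Counter(structures)
    total = sum(counts.values())
    if total == 0:
        raise ValueError("no structures to aggregate: input stream is empty")
    rows = tuple(
        StructureRow(structure=s, count=c, rate=c / total)
        for s, c in sorted(counts.items(), key=lambda kv: (-kv[1], kv[0]))
    )
    return StructureTable(rows=rows, total_reads=total)


def apply_rate_floor(table: StructureTable, floor: float = DEFAULT_RATE_FLOOR) -> FlooredTable:
    """Hide rows with rate below ``floor`` from display; totals unchanged."""
    if not 0.0 <= floor <= 1.0:
        raise ValueError("rate floor must be in [0, 1]")
    shown = tuple(r for r in table.rows if r.rate >= floor)
    hidden = [r for r in table.rows if r.rate < floor]
    return FlooredTable(
        shown=shown,
        hidden_count=len(hidden),
        hidden_rate=sum(r.rate for r in hidden),
        rate_floor=floor,
        total_reads=table.total_reads,
    )
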