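"""File I/O: FastQ input (plain/gzip/bz2), HTML summary, gzip NDJSON detail.

FastQ is read through Biopython's SeqIO in the 4-line Sanger dialect with
Phred+33 qualities; compression is detected from the file's magic bytes,
so a gzip file named ``.fastq`` still opens.  The detail file is
newline-delimited JSON inside a gzip stream — one object per read or pair,
carrying the read name(s), sequence(s), Phred qualities, the segment list,
and (when enabled) the per-segment similarity entries.  The HTML summary
is a single self-contained page: run options, the pattern list with both
strand sequences, the pairwise distance matrix and all warnings, and the
structure table with the rate floor applied.
"""

from __future__ import annotations

import bz2
import gzip
import html
import io
import json
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Iterable, Iterator, Optional

from Bio import SeqIO

from .distance import SegmentSimilarity
from .patterns import Diagnostic, PairwiseDistances, PatternSet
from .search import ReadRecord, ReadStructure, Segment
from .stats import FlooredTable, StructureTable, apply_rate_floor

__all__ = [
    "RunConfig",
    "FastqFormatError",
    "open_maybe_compressed",
    "read_fastq",
    "pair_reads",
    "detail_record",
    "write_detail",
    "read_detail",
    "write_summary",
]

_GZIP_MAGIC = b"\x1f\x8b"
_BZ2_MAGIC = b"BZh"


class FastqFormatError(ValueError):
    """Raised for malformed FastQ input."""


@dataclass
class RunConfig:
    """Everything one analysis run needs; echoed into the HTML summary."""

    r1_path: str
    patterns_source: str
    summary_path: str
    r2_path: Optional[str] = None
    detail_path: Optional[str] = None
    max_kmer_size: Optional[int] = None  # None -> longest pattern + 1
    rate_floor: float = 0.001
    read_analysis_enabled: bool = False
    confusion_threshold: int = 2
    palindrome_risk_threshold: int = 2
    workers: int = 1
    max_reads: Optional[int] = None

    @property
    def paired(self) -> bool:
        return self.r2_path is not None

    def as_dict(self) -> dict:
        return {
            "r1": self.r1_path,
            "r2": self.r2_path,
            "patterns": self.patterns_source,
            "summary": self.summary_path,
            "detail": self.detail_path,
            "mode": "paired-end" if self.paired else "single-end",
            "max_kmer_size": self.max_kmer_size,
            "rate_floor": self.rate_floor,
            "read_analysis_enabled": self.read_analysis_enabled,
            "confusion_threshold": self.confusion_threshold,
            "palindrome_risk_threshold": self.palindrome_risk_threshold,
            "workers": self.workers,
            "max_reads": self.max_reads,
        }


def open_maybe_compressed(path: str | Path, mode: str = "rt") -> IO:
    """Open a possibly gzip- or bz2-compressed file, sniffing magic bytes.

    Detection ignores the file extension, so mislabeled files still open.
    """
    path = Path(path)
    with open(path, "rb") as fh:
        magic = fh.read(3)
    if magic.startswith(_GZIP_MAGIC):
        return gzip.open(path, mode)
    if magic.startswith(_BZ2_MAGIC):
        return bz2.open(path, mode)
    return open(path, mode)


def read_fastq(
    path: str | Path, max_reads: Optional[int] = None, mate: str = "single"
) -> Iterator[ReadRecord]:
    """Stream ReadRecords from a FastQ file in file order.

    Qualities are decoded from the Sanger/Illumina-1.8 Phred+33 encoding.
    Raises :class:`FastqFormatError` for truncated records or
    sequence/quality length mismatches, naming the record.
    """
    count = 0
    with open_maybe_compressed(path, "rt") as handle:
        parser = SeqIO.parse(handle, "fastq")
        index = 0
        while True:
            if max_reads is not None and count >= max_reads:
                return
            try:
                rec = next(parser)
            except StopIteration:
                return
            except ValueError as exc:
                raise FastqFormatError(
                    f"{path}: bad FastQ record #{index + 1}: {exc}"
                ) from exc
            yield ReadRecord(
                read_id=rec.id,
                sequence=str(rec.seq).upper(),
                qualities=tuple(rec.letter_annotations["phred_quality"]),
                mate=mate,
            )
            index += 1
            count += 1


_MATE_DESIGNATOR = re.compile(r"/[12]$")


def _pair_stem(read_id: str) -> str:
    return _MATE_DESIGNATOR.sub("", read_id.split()[0])


def pair_reads(
    s1: Iterable[ReadRecord], s2: Iterable[ReadRecord]
) -> Iterator[tuple[ReadRecord, ReadRecord]]:
    """Zip two mate streams positionally, validating read-ID agreement.

    IDs must agree after stripping a trailing ``/1``/``/2`` designator
    (the space-delimited Illumina comment is already absent from the ID).
    """
    it1, it2 = iter(s1), iter(s2)
    index = 0
    while True:
        r1 = next(it1, None)
        r2 = next(it2, None)
        if r1 is None and r2 is None:
            return
        if r1 is None or r2 is None:
            missing = "R1" if r1 is None else "R2"
            raise FastqFormatError(
                f"paired inputs have different lengths: {missing} stream "
                f"ended at record #{index + 1}"
            )
        if _pair_stem(r1.read_id) != _pair_stem(r2.read_id):
            raise FastqFormatError(
                f"read ID mismatch at record #{index + 1}: "
                f"{r1.read_id!r} vs {r2.read_id!r}"
            )
        yield r1, r2
        index += 1


# ---------------------------------------------------------------------------
# detail file (gzip NDJSON)

def _segment_dict(seg: Segment) -> dict:
    d = {"kind": seg.kind, "start": seg.start, "end": seg.end, "sequence": seg.sequence}
    if seg.kind == "match":
        d["pattern"] = seg.pattern_name
        d["strand"] = seg.strand
    return d


def _similarity_dicts(sims: list[SegmentSimilarity]) -> list[dict]:
    return [
        {
            "segment_index": s.segment_index,
            "pattern": s.pattern_name,
            "strand": s.strand,
            "distance": s.distance,
        }
        for s in sims
    ]


def detail_record(
    reads: list[ReadRecord],
    structures: list[ReadStructure],
    structure_string: str,
    similarities: Optional[list[list[SegmentSimilarity]]] = None,
) -> dict:
    """Build one detail-file object for a read (one mate) or pair (two)."""
    mates = []
    for i, (read, struct) in enumerate(zip(reads, structures)):
        mate = {
            "read_id": read.read_id,
            "sequence": read.sequence,
            "phred_qualities": list(read.qualities),
            "structure": struct.structure_string,
            "segments": [_segment_dict(s) for s in struct.segments],
        }
        if similarities is not None:
            mate["levenshtein"] = _similarity_dicts(similarities[i])
        mates.append(mate)
    return {
        "read_id": _pair_stem(reads[0].read_id),
        "structure": structure_string,
        "mates": mates,
    }


def write_detail(records: Iterable[dict], path: str | Path) -> int:
    """Write detail records as gzip-compressed NDJSON; returns the count."""
    n = 0
    with gzip.open(path, "wt") as fh:
        for rec in records:
            fh.write(json.dumps(rec, separators=(",", ":")))
            fh.write("\n")
            n += 1
    return n


def read_detail(path: str | Path) -> Iterator[dict]:
    """Parse a detail file back into dict records (lossless round trip)."""
    with gzip.open(path, "rt") as fh:
        for line in fh:
            line = line.strip()
            if line:
                yield json.loads(line)


# ---------------------------------------------------------------------------
# HTML summary

_CSS = """
body { font-family: sans-serif; margin: 2em; color: #222; }
h1 { font-size: 1.5em; } h2 { font-size: 1.2em; margin-top: 1.5em; }
table { border-collapse: collapse; margin: 0.5em 0; }
th, td { border: 1px solid #999; padding: 0.25em 0.6em; text-align: left; }
th { background: #eee; }
td.num { text-align: right; font-variant-numeric: tabular-nums; }
code { background: #f4f4f4; padding: 0 0.2em; }
.warn { color: #a33; }
.residual td { font-style: italic; color: #555; }
"""


def _fmt_pct(rate: float) -> str:
    """Percentage with 4 significant digits."""
    return f"{rate * 100:.4g}%"


def _esc(x: object) -> str:
    return html.escape(str(x))


def _options_rows(config: RunConfig) -> str:
    rows = []
    for key, value in config.as_dict().items():
        rows.append(f"<tr><th>{_esc(key)}</th><td>{_esc(value)}</td></tr>")
    return "\n".join(rows)


def _pattern_rows(ps: PatternSet) -> str:
    rows = []
    for p in ps:
        pal = "yes" if p.is_palindromic else "no"
        rows.append(
            f"<tr><td>{_esc(p.name)}</td><td class='num'>{p.length}</td>"
            f"<td><code>{_esc(p.sequence)}</code></td>"
            f"<td><code>{_esc(p.revcomp)}</code></td><td>{pal}</td></tr>"
        )
    return "\n".join(rows)


def _warning_items(warnings: list[Diagnostic]) -> str:
    if not warnings:
        return "<p>No pattern warnings.</p>"
    items = "\n".join(f"<li class='warn'>[{_esc(w.kind)}] {_esc(w.message)}</li>" for w in warnings)
    return f"<ul>\n{items}\n</ul>"


def _strand_pair_rows(dists: PairwiseDistances) -> str:
    rows = []
    for (a, b), combos in dists.by_strand.items():
        cells = "".join(
            f"<td class='num'>{combos[(sa, sb)]}</td>"
            for sa, sb in (("F", "F"), ("F", "R"), ("R", "F"), ("R", "R"))
        )
        rows.append(
            f"<tr><td>{_esc(a)}</td><td>{_esc(b)}</td>{cells}"
            f"<td class='num'>{min(combos.values())}</td></tr>"
        )
    return "\n".join(rows)


def _structure_rows(view: FlooredTable) -> str:
    rows = []
    for r in view.shown:
        rows.append(
            f"<tr><td><code>{_esc(r.structure)}</code></td>"
            f"<td class='num'>{r.count}</td>"
            f"<td class='num'>{_fmt_pct(r.rate)}</td></tr>"
        )
    if view.hidden_count:
        rows.append(
            f"<tr class='residual'><td>{view.hidden_count} structure(s) below "
            f"rate floor {view.rate_floor}</td>"
            f"<td class='num'>&mdash;</td>"
            f"<td class='num'>{_fmt_pct(view.hidden_rate)}</td></tr>"
        )
    return "\n".join(rows)


def write_summary(
    config: RunConfig,
    ps: PatternSet,
    warnings: list[Diagnostic],
    pair_distances: Optional[PairwiseDistances],
    table: StructureTable,
    path: str | Path | None = None,
) -> str:
    """Render the self-contained HTML summary; write it if a path is given.

    Returns the HTML text.  Content comprises the echoed run options, the
    pattern list (lengths and both strand sequences), the pairwise
    Levenshtein distances with all diagnostics, and the structure table
    under the configured rate floor with a residual line.
    """
    view = apply_rate_floor(table, config.rate_floor)
    unit = "pairs" if config.paired else "reads"

    matrix_html = ""
    if pair_distances is not None and len(pair_distances.names) > 1:
        matrix_html = (
            "<h2>Pattern pair Levenshtein distances</h2>\n"
            + pair_distances.min_matrix.to_html(
                classes="dist", border=1, justify="left"
            )
            + "\n<p>Minimum over strand combinations; per-combination distances "
            "(F = sequence, R = reverse complement):</p>\n"
            "<table><tr><th>pattern A</th><th>pattern B</th><th>F-F</th>"
            "<th>F-R</th><th>R-F</th><th>R-R</th><th>min</th></tr>\n"
            + _strand_pair_rows(pair_distances)
            + "\n</table>"
        )

    doc = f"""<!DOCTYPE html>
<html lang="en">
<head>
<meta charset="utf-8">
<title>Read structure summary</title>
<style>{_CSS}</style>
</head>
<body>
<h1>Read structure summary</h1>

<h2>Run options</h2>
<table>
{_options_rows(config)}
</table>

<h2>Patterns</h2>
<table>
<tr><th>name</th><th>length (bp)</th><th>forward</th><th>reverse complement</th><th>palindromic</th></tr>
{_pattern_rows(ps)}
</table>

<h2>Pattern warnings</h2>
{_warning_items(warnings)}

{matrix_html}

<h2>Read structures ({table.total_reads} {unit})</h2>
<table>
<tr><th>structure</th><th>count</th><th>percentage</th></tr>
{_structure_rows(view)}
</table>
</body>
</html>
"""
    if path is not None:
        Path(path).write_text(doc)
    return doc
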