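"""Levenshtein edit distance and the optional per-read similarity analysis.

The per-read analysis is a diagnostic aid: for every unrecognized segment
(k-mer or unknown stretch) it reports the edit distance to every pattern on
both strands, so a user can judge whether an unrecognized stretch is in
fact a pattern copy corrupted by sequencing errors.  It is a coarse
similarity measure — whole segment against whole pattern, no windowing —
and is disabled by default because it dominates run time on large inputs.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import TYPE_CHECKING

import edlib

if TYPE_CHECKING:
    from .patterns import PatternSet
    from .search import ReadStructure

__all__ = ["levenshtein", "SegmentSimilarity", "analyze_read_segments"]


def levenshtein(a: str, b: str) -> int:
    """Unit-cost Levenshtein edit distance between two strings."""
    if a == b:
        return 0
    if not a or not b:
        return len(a) + len(b)
    return edlib.align(a, b, task="distance", mode="NW")["editDistance"]


@dataclass(frozen=True)
class SegmentSimilarity:
    """Edit distance between one unrecognized segment and one pattern strand."""

    segment_index: int
    pattern_name: str
    strand: str  # "F" compares against the pattern sequence, "R" its revcomp
    distance: int


def analyze_read_segments(
    structure: "ReadStructure", ps: "PatternSet"
) -> list[SegmentSimilarity]:
    """Compare every kmer/unknown segment against every pattern, both strands.

    Match segments are skipped (their distance to the matched pattern is
    trivially zero and to others uninformative).  Results are ordered by
    segment position, then pattern order, then strand F before R.
    """
    out: list[SegmentSimilarity] = []
    for idx, seg in enumerate(structure.segments):
        if seg.kind == "match":
            continue
        for p in ps:
            out.append(
                SegmentSimilarity(idx, p.name, "F", levenshtein(seg.sequence, p.sequence))
            )
            out.append(
                SegmentSimilarity(idx, p.name, "R", levenshtein(seg.sequence, p.revcomp))
            )
    return out
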