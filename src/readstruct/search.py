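"""Core segmentation engine: decompose a read into pattern matches, k-mers
and unknown stretches, and render the canonical structure string.

The algorithm is exact find-and-mask.  Patterns are processed in user
order; within one pattern the forward strand (the sequence itself) is
searched before the reverse strand (its reverse complement).  Each pass
scans left to right and claims every exact occurrence that lies entirely
in unclaimed territory; an occurrence overlapping any already-claimed base
is skipped whole — matching is full-match only, so a single sequencing
error makes a pattern copy invisible to the search.  After all passes,
every maximal unclaimed stretch becomes one segment: a length-labeled
k-mer if it is short enough (at most ``max_kmer_size``), otherwise an
unknown.  The segments tile the read exactly.

K-mer labeling exists because oligo synthesis errors and enzymatic steps
such as A-tailing produce pattern copies one base shorter or longer than
expected; a ``{kmer:14bp}`` token next to a 15 bp pattern is a strong hint.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

from .patterns import PatternSet

__all__ = [
    "ReadRecord",
    "Segment",
    "ReadStructure",
    "default_max_kmer_size",
    "segment_read",
    "segment_pair",
    "render_structure",
    "render_pair",
]


@dataclass(frozen=True)
class ReadRecord:
    """One FastQ record: identifier, sequence and Phred qualities."""

    read_id: str
    sequence: str
    qualities: tuple[int, ...]
    mate: str = "single"  # "R1" | "R2" | "single"

    def __post_init__(self) -> None:
        if len(self.qualities) != len(self.sequence):
            raise ValueError(
                f"read {self.read_id!r}: quality length {len(self.qualities)} "
                f"!= sequence length {len(self.sequence)}"
            )


@dataclass(frozen=True)
class Segment:
    """One fragment of a read: a pattern match, a k-mer, or an unknown.

    Coordinates are 0-based, half-open.  ``strand`` is set only for matches
    of non-palindromic patterns ("F" = forward sequence, "R" = reverse
    complement found in the read).
    """

    kind: str  # "match" | "kmer" | "unknown"
    start: int
    end: int
    sequence: str
    pattern_name: Optional[str] = None
    strand: Optional[str] = None

    @property
    def length(self) -> int:
        return self.end - self.start

    def token(self) -> str:
        """Canonical structure-string token for this segment."""
        if self.kind == "match":
            if self.strand is None:  # palindromic: no meaningful strand
                return "{%s}" % self.pattern_name
            return "{%s:%s}" % (self.pattern_name, self.strand)
        if self.kind == "kmer":
            return "{kmer:%dbp}" % self.length
        return "{unknown}"


@dataclass(frozen=True)
class ReadStructure:
    """Ordered segmentation of one read plus its canonical string form."""

    segments: tuple[Segment, ...]
    structure_string: str


def default_max_kmer_size(ps: PatternSet) -> int:
    """Longest pattern length + 1, so every ±1 bp pattern variant gets a
    length label rather than collapsing into ``{unknown}``."""
    return ps.max_length + 1


def render_structure(structure: ReadStructure, ps: PatternSet | None = None) -> str:
    """Canonical structure string: concatenated per-segment tokens."""
    return "".join(seg.token() for seg in structure.segments)


def segment_read(
    read: ReadRecord, ps: PatternSet, max_kmer_size: int | None = None
) -> ReadStructure:
    """Segment one read by ordered find-and-mask pattern search.

    Parameters
    ----------
    read:
        The read to segment; must be non-empty.
    ps:
        Ordered pattern set; search order is user order, forward strand
        before reverse strand within each pattern.  Palindromic patterns
        are searched once (both strands are identical).
    max_kmer_size:
        Unclaimed stretches up to this length are labeled ``{kmer:Nbp}``,
        longer ones ``{unknown}``.  Defaults to the longest pattern + 1.
    """
    seq = read.sequence
    n = len(seq)
    if n == 0:
        raise ValueError(f"read {read.read_id!r} is empty")
    if len(ps) == 0:
        raise ValueError("pattern set is empty")
    if max_kmer_size is None:
        max_kmer_size = default_max_kmer_size(ps)

    claimed = bytearray(n)
    matches: list[Segment] = []
    for p in ps:
        passes = [("F", p.sequence)]
        if not p.is_palindromic:
            passes.append(("R", p.revcomp))
        for strand, needle in passes:
            length = len(needle)
            pos = 0
            while True:
                i = seq.find(needle, pos)
                if i < 0:
                    break
                if any(claimed[i : i + length]):
                    # overlaps a claimed span: skip this occurrence whole
                    pos = i + 1
                    continue
                for k in range(i, i + length):
                    claimed[k] = 1
                matches.append(
                    Segment(
                        kind="match",
                        start=i,
                        end=i + length,
                        sequence=needle,
                        pattern_name=p.name,
                        strand=None if p.is_palindromic else strand,
                    )
                )
                pos = i + length

    matches.sort(key=lambda s: s.start)
    segments: list[Segment] = []
    cursor = 0
    for m in matches + [None]:  # sentinel closes the trailing gap
        gap_end = n if m is None else m.start
        if gap_end > cursor:
            kind = "kmer" if gap_end - cursor <= max_kmer_size else "unknown"
            segments.append(
                Segment(kind=kind, start=cursor, end=gap_end, sequence=seq[cursor:gap_end])
            )
        if m is not None:
            segments.append(m)
            cursor = m.end
        else:
            cursor = gap_end

    structure = ReadStructure(segments=tuple(segments), structure_string="")
    rendered = render_structure(structure)
    return ReadStructure(segments=tuple(segments), structure_string=rendered)


_MATE_SUFFIXES = ("/1", "/2")


def _id_stem(read_id: str) -> str:
    stem = read_id.split()[0] if read_id else read_id
    for suf in _MATE_SUFFIXES:
        if stem.endswith(suf):
            return stem[: -len(suf)]
    return stem


def render_pair(s1: ReadStructure, s2: ReadStructure) -> str:
    return f"R1:{s1.structure_string} R2:{s2.structure_string}"


def segment_pair(
    r1: ReadRecord,
    r2: ReadRecord,
    ps: PatternSet,
    max_kmer_size: int | None = None,
) -> tuple[ReadStructure, ReadStructure, str]:
    """Segment both mates of a pair independently.

    R2 is searched in machine orientation, never reverse-complemented:
    both pattern strands are searched anyway, so orientation shows up as
    the strand suffix instead.  The pair is counted as a single structure
    unit with the string ``"R1:<...> R2:<...>"``.
    """
    stem1, stem2 = _id_stem(r1.read_id), _id_stem(r2.read_id)
    if stem1 != stem2:
        raise ValueError(f"mate ID mismatch: {r1.read_id!r} vs {r2.read_id!r}")
    s1 = segment_read(r1, ps, max_kmer_size)
    s2 = segment_read(r2, ps, max_kmer_size)
    return s1, s2, render_pair(s1, s2)
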