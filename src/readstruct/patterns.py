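"""Pattern dictionary parsing, validation, and pre-run diagnostics.

Patterns are the named service sequences (adapters, primers, barcodes) the
user wants located in reads.  They are supplied as a JSON object whose key
order is significant: patterns are searched in exactly that order, and a
long-to-short ordering is the recommended layout when sequences overlap or
nest.  Before any read is touched, the set is screened for three classes of
trouble:

* ordering  — a shorter pattern listed before a longer one can shadow it;
* confusability — two patterns within a few edits of each other (on any
  strand combination) may be swapped by sequencing errors, and one pattern
  contained in another can never be matched inside the longer one's span;
* palindromes — a sequence equal to its own reverse complement carries no
  usable strand information, and a sequence within a few edits of its own
  reverse complement can *become* palindromic through sequencing errors,
  biasing forward/reverse statistics.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterator

import pandas as pd

from .distance import levenshtein

__all__ = [
    "Pattern",
    "PatternSet",
    "Diagnostic",
    "PairwiseDistances",
    "PatternError",
    "reverse_complement",
    "parse_pattern_set",
    "check_order",
    "analyze_pattern_pairs",
    "analyze_palindromes",
]

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_VALID_BASES = frozenset("ACGT")

#: default edit-distance thresholds for the confusability / palindrome-risk
#: diagnostics ("a few sequencing errors")
DEFAULT_CONFUSION_THRESHOLD = 2
DEFAULT_PALINDROME_RISK_THRESHOLD = 2


class PatternError(ValueError):
    """Raised for malformed or invalid pattern input."""


def reverse_complement(sequence: str) -> str:
    """Reverse complement of an uppercase A/C/G/T string."""
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Pattern:
    """One named service sequence with its precomputed reverse complement.

    ``is_palindromic`` flags reverse-complement palindromes (sequence equal
    to its own reverse complement, necessarily even-length); such patterns
    are searched on one strand only and rendered without a strand suffix.
    """

    name: str
    sequence: str
    revcomp: str
    length: int
    is_palindromic: bool

    @classmethod
    def from_sequence(cls, name: str, sequence: str) -> "Pattern":
        seq = sequence.upper()
        if not seq:
            raise PatternError(f"pattern {name!r}: sequence is empty")
        bad = set(seq) - _VALID_BASES
        if bad:
            raise PatternError(
                f"pattern {name!r}: invalid character(s) "
                f"{', '.join(sorted(bad))!s} (only A/C/G/T are allowed)"
            )
        rc = reverse_complement(seq)
        return cls(
            name=name,
            sequence=seq,
            revcomp=rc,
            length=len(seq),
            is_palindromic=seq == rc,
        )


@dataclass(frozen=True)
class Diagnostic:
    """One pattern-set warning.

    kind is one of ``not-sorted``, ``near-match``, ``nested``,
    ``palindrome``, ``near-palindrome``; ``members`` names the pattern(s)
    involved and ``distance`` carries the edit distance where applicable.
    """

    kind: str
    members: tuple[str, ...]
    message: str
    distance: int | None = None


@dataclass
class PatternSet:
    """Ordered pattern collection; order equals the input JSON key order."""

    patterns: list[Pattern]
    warnings: list[Diagnostic] = field(default_factory=list)

    def __post_init__(self) -> None:
        names = [p.name for p in self.patterns]
        if len(names) != len(set(names)):
            raise PatternError("duplicate pattern names")

    def __iter__(self) -> Iterator[Pattern]:
        return iter(self.patterns)

    def __len__(self) -> int:
        return len(self.patterns)

    def __getitem__(self, name: str) -> Pattern:
        for p in self.patterns:
            if p.name == name:
                return p
        raise KeyError(name)

    @property
    def names(self) -> list[str]:
        return [p.name for p in self.patterns]

    @property
    def max_length(self) -> int:
        return max(p.length for p in self.patterns)


def parse_pattern_set(json_text: str) -> PatternSet:
    """Parse a JSON object of ``name -> nucleotide sequence`` pairs.

    Key order is preserved.  Sequences are case-insensitive on input and
    canonicalized to uppercase.  Raises :class:`PatternError` for malformed
    JSON (with position), non-A/C/G/T characters (naming pattern and
    character), duplicate names, or an empty object.
    """

    def _no_dupes(pairs):
        seen = set()
        for key, _ in pairs:
            if key in seen:
                raise PatternError(f"duplicate pattern name {key!r}")
            seen.add(key)
        return dict(pairs)

    try:
        obj = json.loads(json_text, object_pairs_hook=_no_dupes)
    except PatternError:
        raise
    except json.JSONDecodeError as exc:
        raise PatternError(
            f"malformed pattern JSON at line {exc.lineno}, column {exc.colno}: "
            f"{exc.msg}"
        ) from exc
    if not isinstance(obj, dict):
        raise PatternError("pattern input must be a JSON object of name: sequence pairs")
    if not obj:
        raise PatternError("pattern object is empty")
    patterns = []
    for name, seq in obj.items():
        if not isinstance(seq, str):
            raise PatternError(f"pattern {name!r}: sequence must be a string")
        patterns.append(Pattern.from_sequence(name, seq))
    return PatternSet(patterns=patterns)


def check_order(ps: PatternSet) -> list[Diagnostic]:
    """Warn if patterns are not sorted long to short.

    Long-to-short is the safe ordering for overlapping or nested sequences
    (a shorter pattern claimed first can mask a longer one).  Only the first
    offending adjacent pair is reported; equal lengths are fine.
    """
    for a, b in zip(ps.patterns, ps.patterns[1:]):
        if a.length < b.length:
            return [
                Diagnostic(
                    kind="not-sorted",
                    members=(a.name, b.name),
                    message=(
                        f"patterns are not sorted from long to short: "
                        f"{a.name!r} ({a.length} bp) precedes {b.name!r} "
                        f"({b.length} bp); the earlier, shorter pattern may "
                        f"mask occurrences of the later, longer one"
                    ),
                )
            ]
    return []


@dataclass
class PairwiseDistances:
    """All-pairs Levenshtein distances between pattern sequences.

    ``by_strand[(a, b)]`` maps each of the four strand combinations
    ``("F","F")``, ``("F","R")``, ``("R","F")``, ``("R","R")`` to its edit
    distance; ``min_matrix`` is the symmetric matrix of per-pair minima.
    """

    names: list[str]
    by_strand: dict[tuple[str, str], dict[tuple[str, str], int]]
    min_matrix: pd.DataFrame

    def minimum(self, a: str, b: str) -> int:
        return int(self.min_matrix.loc[a, b])


def analyze_pattern_pairs(
    ps: PatternSet,
    confusion_threshold: int = DEFAULT_CONFUSION_THRESHOLD,
) -> tuple[list[Diagnostic], PairwiseDistances]:
    """Screen every pattern pair for confusability and nesting.

    For each unordered pair the edit distance is computed for all four
    strand combinations and the minimum is reported; a pair whose minimum
    is at or below ``confusion_threshold`` draws a ``near-match`` warning
    (sequencing errors could interconvert the two).  A pattern whose
    sequence or reverse complement is a substring of another pattern draws
    a ``nested`` warning: the inner pattern can never be matched inside the
    outer one's claimed span.
    """
    if confusion_threshold < 0:
        raise ValueError("confusion_threshold must be >= 0")
    names = ps.names
    n = len(names)
    mat = pd.DataFrame(0, index=names, columns=names, dtype=int)
    by_strand: dict[tuple[str, str], dict[tuple[str, str], int]] = {}
    warnings: list[Diagnostic] = []
    for i in range(n):
        a = ps.patterns[i]
        for j in range(i + 1, n):
            b = ps.patterns[j]
            combos = {
                ("F", "F"): levenshtein(a.sequence, b.sequence),
                ("F", "R"): levenshtein(a.sequence, b.revcomp),
                ("R", "F"): levenshtein(a.revcomp, b.sequence),
                ("R", "R"): levenshtein(a.revcomp, b.revcomp),
            }
            by_strand[(a.name, b.name)] = combos
            dmin = min(combos.values())
            mat.loc[a.name, b.name] = dmin
            mat.loc[b.name, a.name] = dmin
            if dmin <= confusion_threshold:
                warnings.append(
                    Diagnostic(
                        kind="near-match",
                        members=(a.name, b.name),
                        distance=dmin,
                        message=(
                            f"patterns {a.name!r} and {b.name!r} are within "
                            f"{dmin} edit(s) of each other (minimum over "
                            f"strand combinations); sequencing errors may "
                            f"confuse them"
                        ),
                    )
                )
            inner, outer = (a, b) if a.length <= b.length else (b, a)
            if inner.length < outer.length and (
                inner.sequence in outer.sequence
                or inner.sequence in outer.revcomp
                or inner.revcomp in outer.sequence
                or inner.revcomp in outer.revcomp
            ):
                warnings.append(
                    Diagnostic(
                        kind="nested",
                        members=(inner.name, outer.name),
                        message=(
                            f"pattern {inner.name!r} is nested inside "
                            f"{outer.name!r} (substring on some strand); it "
                            f"cannot be matched within the longer pattern's "
                            f"span"
                        ),
                    )
                )
    return warnings, PairwiseDistances(names=names, by_strand=by_strand, min_matrix=mat)


def analyze_palindromes(
    ps: PatternSet,
    palindrome_risk_threshold: int = DEFAULT_PALINDROME_RISK_THRESHOLD,
) -> list[Diagnostic]:
    """Flag reverse-complement palindromes and near-palindromes.

    A palindromic pattern (sequence equal to its own reverse complement)
    has no meaningful strand, and a sequence within
    ``palindrome_risk_threshold`` edits of its own reverse complement can
    become palindromic through sequencing errors; either situation distorts
    forward/reverse orientation statistics.
    """
    if palindrome_risk_threshold < 1:
        raise ValueError("palindrome_risk_threshold must be >= 1")
    warnings: list[Diagnostic] = []
    for p in ps.patterns:
        if p.is_palindromic:
            warnings.append(
                Diagnostic(
                    kind="palindrome",
                    members=(p.name,),
                    distance=0,
                    message=(
                        f"pattern {p.name!r} is a reverse-complement "
                        f"palindrome; matches carry no strand information"
                    ),
                )
            )
        else:
            d = levenshtein(p.sequence, p.revcomp)
            if d <= palindrome_risk_threshold:
                warnings.append(
                    Diagnostic(
                        kind="near-palindrome",
                        members=(p.name,),
                        distance=d,
                        message=(
                            f"pattern {p.name!r} is within {d} edit(s) of its "
                            f"own reverse complement and may become "
                            f"palindromic through sequencing errors"
                        ),
                    )
                )
    return warnings
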