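"""Shared fixtures and independent oracles.

The oracles here are deliberately written from scratch, in a different
style from the library code (slicing-based scanning, full-matrix DP), so
that agreement between library and oracle is meaningful.
"""

from __future__ import annotations

import random

import pytest

from readstruct import parse_pattern_set

FOO_BAR_BAZ = '{"foo": "CTGTCTCTTATACAC", "bar": "CCGAAAACACG", "baz": "TCGTCGGG"}'

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}


def rc(seq: str) -> str:
    return "".join(_COMP[b] for b in reversed(seq))


def dp_levenshtein(a: str, b: str) -> int:
    """Quadratic dynamic-programming edit distance (independent oracle)."""
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i]
        for j, cb in enumerate(b, 1):
            cur.append(
                min(
                    prev[j] + 1,
                    cur[j - 1] + 1,
                    prev[j - 1] + (ca != cb),
                )
            )
        prev = cur
    return prev[-1]


def oracle_segment_tokens(seq: str, pattern_json_pairs, max_kmer: int) -> str:
    """Brute-force find-and-mask segmentation, replayed naively.

    ``pattern_json_pairs`` is a list of (name, forward_sequence).  Scans
    every start position with string slicing; claims occurrences leftmost
    first, skipping any that touch claimed bases; then renders the token
    string with k-mer/unknown labeling of the leftover stretches.
    """
    n = len(seq)
    claimed: set[int] = set()
    matches = []
    for name, fwd in pattern_json_pairs:
        fwd = fwd.upper()
        rev = rc(fwd)
        palindromic = fwd == rev
        needles = [("F", fwd)] if palindromic else [("F", fwd), ("R", rev)]
        for strand, needle in needles:
            L = len(needle)
            i = 0
            while i + L <= n:
                if seq[i : i + L] == needle and not (claimed & set(range(i, i + L))):
                    claimed.update(range(i, i + L))
                    matches.append((i, i + L, name, None if palindromic else strand))
                    i += L
                else:
                    i += 1
    matches.sort()
    tokens = []
    cursor = 0
    for start, end, name, strand in matches + [(n, n, None, None)]:
        if start > cursor:
            gap = start - cursor
            tokens.append(f"{{kmer:{gap}bp}}" if gap <= max_kmer else "{unknown}")
        if name is not None:
            tokens.append(f"{{{name}}}" if strand is None else f"{{{name}:{strand}}}")
        cursor = max(cursor, end)
    return "".join(tokens)


def random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice("ACGT") for _ in range(length))


def make_planted_read(rng: random.Random, pattern_seqs: list[str]) -> str:
    """Random read of length 50-150 with 0-3 pattern copies pasted in at
    random positions and strands (overlaps between copies allowed)."""
    length = rng.randint(50, 150)
    seq = list(random_dna(rng, length))
    for _ in range(rng.randint(0, 3)):
        copy = rng.choice(pattern_seqs)
        if rng.random() < 0.5:
            copy = rc(copy)
        if len(copy) <= length:
            start = rng.randint(0, length - len(copy))
            seq[start : start + len(copy)] = copy
    return "".join(seq)


@pytest.fixture(scope="session")
def foobar_ps():
    """The canonical three-pattern example set (15 / 11 / 8 bp)."""
    return parse_pattern_set(FOO_BAR_BAZ)


@pytest.fixture(scope="session")
def foobar_pairs():
    return [("foo", "CTGTCTCTTATACAC"), ("bar", "CCGAAAACACG"), ("baz", "TCGTCGGG")]
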