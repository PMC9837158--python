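"""Synthetic FastQ generator with planted, truth-labeled read structures.

Reads are assembled from templates — ordered mixes of pattern tokens
(placed on a chosen strand, optionally truncated/extended by one base or
hit with point substitutions, mimicking A-tailing and synthesis errors)
and random filler stretches.  For error-free templates the expected
structure string is known exactly, which makes generated files usable as
ground truth for the segmentation engine.

Truth validity demands more than pattern-free fillers: a pattern occurrence
could straddle a filler/pattern junction, or a mutated copy could recreate
a different pattern.  The generator therefore rejection-samples whole
reads — a candidate read is accepted only if every pattern occurrence on
either strand coincides exactly with a planted intact copy.  This fails
(by design, with an error) for pattern sets where one pattern contains
another, since nested occurrences can never be excluded.

Qualities are constant Phred 37: this tool treats qualities as
pass-through data, so realistic quality profiles are out of scope.
"""

from __future__ import annotations

import gzip
import random
from dataclasses import dataclass, field
from pathlib import Path
from typing import IO, Optional, Sequence, Union

from .patterns import PatternSet
from .search import default_max_kmer_size

__all__ = [
    "PatternToken",
    "FillerToken",
    "StructureTemplate",
    "TruthRecord",
    "GeneratedDataset",
    "generate",
]

_BASES = "ACGT"
_PHRED37_CHAR = chr(37 + 33)  # "F"
_MAX_ATTEMPTS = 1000


@dataclass(frozen=True)
class PatternToken:
    """Plant one copy of a named pattern.

    ``strand`` places the forward sequence ("F") or its reverse complement
    ("R").  ``delta`` of -1/+1 trims the last base or appends a random one
    (the ±1 bp variants produced by A-tailing and synthesis errors);
    ``substitutions`` injects that many random point mutations into the
    copy.  A token with any modification is no longer an exact pattern
    copy and is expected to surface as k-mer/unknown content.
    """

    name: str
    strand: str = "F"
    delta: int = 0
    substitutions: int = 0

    @property
    def exact(self) -> bool:
        return self.delta == 0 and self.substitutions == 0


@dataclass(frozen=True)
class FillerToken:
    """Random pattern-free stretch with length uniform in [min_len, max_len]."""

    min_len: int
    max_len: int


Token = Union[PatternToken, FillerToken]


@dataclass(frozen=True)
class StructureTemplate:
    """One read (or pair) layout with a sampling weight.

    ``error_rate`` is a per-base substitution probability applied to the
    whole assembled read; any nonzero rate makes the expected structure
    undefined (truth recorded as None).  ``tokens_r2`` supplies the R2
    layout in paired mode.
    """

    template_id: str
    tokens: tuple[Token, ...]
    tokens_r2: Optional[tuple[Token, ...]] = None
    error_rate: float = 0.0
    weight: float = 1.0


@dataclass(frozen=True)
class TruthRecord:
    read_id: str
    template_id: str
    expected_structure: Optional[str]  # None when error_rate > 0


@dataclass
class GeneratedDataset:
    r1_path: Path
    truth_path: Path
    r2_path: Optional[Path] = None
    truth: list[TruthRecord] = field(default_factory=list)

    @property
    def expected(self) -> dict[str, Optional[str]]:
        return {t.read_id: t.expected_structure for t in self.truth}


def _random_dna(rng: random.Random, length: int) -> str:
    return "".join(rng.choice(_BASES) for _ in range(length))


def _substitute(rng: random.Random, seq: str, pos: int) -> str:
    old = seq[pos]
    new = rng.choice([b for b in _BASES if b != old])
    return seq[:pos] + new + seq[pos + 1 :]


def _realize_token(token: Token, ps: PatternSet, rng: random.Random) -> tuple[str, bool, Optional[PatternToken]]:
    """Return (content, is_exact_pattern_copy, source token or None)."""
    if isinstance(token, FillerToken):
        length = rng.randint(token.min_len, token.max_len)
        return _random_dna(rng, length), False, None
    p = ps[token.name]
    content = p.sequence if token.strand == "F" else p.revcomp
    if token.delta == -1:
        content = content[:-1]
    elif token.delta == 1:
        content = content + rng.choice(_BASES)
    elif token.delta != 0:
        raise ValueError(f"delta must be -1, 0 or +1, got {token.delta}")
    for _ in range(token.substitutions):
        content = _substitute(rng, content, rng.randrange(len(content)))
    return content, token.exact, token


def _assemble(
    tokens: Sequence[Token], ps: PatternSet, rng: random.Random
) -> tuple[str, list[tuple[int, int, str, Optional[str]]], list[tuple[int, int, bool, Optional[PatternToken]]]]:
    """Build one read; returns (sequence, planted match spans, full layout)."""
    parts: list[str] = []
    planted: list[tuple[int, int, str, Optional[str]]] = []
    layout: list[tuple[int, int, bool, Optional[PatternToken]]] = []
    pos = 0
    for token in tokens:
        content, exact, src = _realize_token(token, ps, rng)
        end = pos + len(content)
        if exact and src is not None:
            p = ps[src.name]
            strand = None if p.is_palindromic else src.strand
            planted.append((pos, end, src.name, strand))
        layout.append((pos, end, exact, src))
        parts.append(content)
        pos = end
    seq = "".join(parts)
    if not seq:
        raise ValueError("template produced an empty read")
    return seq, planted, layout


def _occurrences_clean(
    seq: str, ps: PatternSet, planted: list[tuple[int, int, str, Optional[str]]]
) -> bool:
    """True iff every pattern occurrence coincides with a planted copy."""
    planted_set = set(planted)
    for p in ps:
        needles = [("F", p.sequence)]
        if not p.is_palindromic:
            needles.append(("R", p.revcomp))
        for strand, needle in needles:
            want_strand = None if p.is_palindromic else strand
            pos = 0
            while True:
                i = seq.find(needle, pos)
                if i < 0:
                    break
                if (i, i + len(needle), p.name, want_strand) not in planted_set:
                    return False
                pos = i + 1
    return True


def _expected_structure(
    layout: list[tuple[int, int, bool, Optional[PatternToken]]],
    ps: PatternSet,
    max_kmer_size: int,
) -> str:
    """Structure string forced by an error-free layout: exact pattern
    tokens render as matches; maximal runs of everything else render as
    k-mer or unknown by total run length."""
    tokens: list[str] = []
    run_len = 0
    for start, end, exact, src in layout:
        if exact and src is not None:
            if run_len:
                kind = "kmer" if run_len <= max_kmer_size else "unknown"
                tokens.append("{kmer:%dbp}" % run_len if kind == "kmer" else "{unknown}")
                run_len = 0
            p = ps[src.name]
            if p.is_palindromic:
                tokens.append("{%s}" % src.name)
            else:
                tokens.append("{%s:%s}" % (src.name, src.strand))
        else:
            run_len += end - start
    if run_len:
        tokens.append("{kmer:%dbp}" % run_len if run_len <= max_kmer_size else "{unknown}")
    return "".join(tokens)


def _simulate_read(
    template: StructureTemplate,
    tokens: Sequence[Token],
    ps: PatternSet,
    rng: random.Random,
    max_kmer_size: int,
) -> tuple[str, Optional[str]]:
    """One accepted read sequence plus its expected structure (or None)."""
    for _ in range(_MAX_ATTEMPTS):
        seq, planted, layout = _assemble(tokens, ps, rng)
        if template.error_rate > 0.0:
            chars = list(seq)
            for i in range(len(chars)):
                if rng.random() < template.error_rate:
                    chars[i] = rng.choice([b for b in _BASES if b != chars[i]])
            return "".join(chars), None
        if _occurrences_clean(seq, ps, planted):
            return seq, _expected_structure(layout, ps, max_kmer_size)
    raise RuntimeError(
        f"template {template.template_id!r}: could not sample a read whose "
        f"pattern occurrences are exactly the planted copies after "
        f"{_MAX_ATTEMPTS} attempts (nested or highly repetitive patterns?)"
    )


def _open_out(path: Path) -> IO[str]:
    if path.suffix == ".gz":
        return gzip.open(path, "wt")
    return open(path, "w")


def _write_record(fh: IO[str], read_id: str, seq: str) -> None:
    fh.write(f"@{read_id}\n{seq}\n+\n{_PHRED37_CHAR * len(seq)}\n")


def generate(
    templates: Sequence[StructureTemplate],
    n_reads: int,
    seed: int,
    ps: PatternSet,
    out_dir: str | Path,
    paired: bool = False,
    gzip_output: bool = False,
    max_kmer_size: Optional[int] = None,
    prefix: str = "sim",
) -> GeneratedDataset:
    """Write FastQ file(s) plus a truth table of expected structures.

    Deterministic given ``seed``.  Template choice per read follows the
    template weights.  The truth TSV has columns read_id, template_id,
    expected_structure (``NA`` when the template carries errors).  In
    paired mode the expected structure is the pair string
    ``"R1:<...> R2:<...>"`` and mate files carry ``/1``/``/2`` IDs.
    """
    if n_reads < 1:
        raise ValueError("n_reads must be >= 1")
    total_weight = sum(t.weight for t in templates)
    if abs(total_weight - 1.0) > 1e-9:
        raise ValueError(f"template weights must sum to 1 (got {total_weight})")
    if paired and any(t.tokens_r2 is None for t in templates):
        raise ValueError("paired mode requires tokens_r2 on every template")
    if max_kmer_size is None:
        max_kmer_size = default_max_kmer_size(ps)

    rng = random.Random(seed)
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    ext = ".fastq.gz" if gzip_output else ".fastq"
    r1_path = out_dir / f"{prefix}_R1{ext}" if paired else out_dir / f"{prefix}{ext}"
    r2_path = out_dir / f"{prefix}_R2{ext}" if paired else None
    truth_path = out_dir / f"{prefix}_truth.tsv"

    truth: list[TruthRecord] = []
    weights = [t.weight for t in templates]
    with _open_out(r1_path) as f1, (
        _open_out(r2_path) if r2_path else open("/dev/null", "w")
    ) as f2, open(truth_path, "w") as ft:
        ft.write("read_id\ttemplate_id\texpected_structure\n")
        for i in range(n_reads):
            template = rng.choices(templates, weights=weights, k=1)[0]
            stem = f"{prefix}{i:06d}"
            seq1, exp1 = _simulate_read(
                template, template.tokens, ps, rng, max_kmer_size
            )
            if paired:
                seq2, exp2 = _simulate_read(
                    template, template.tokens_r2, ps, rng, max_kmer_size
                )
                expected = (
                    f"R1:{exp1} R2:{exp2}"
                    if exp1 is not None and exp2 is not None
                    else None
                )
                _write_record(f1, f"{stem}/1", seq1)
                _write_record(f2, f"{stem}/2", seq2)
            else:
                expected = exp1
                _write_record(f1, stem, seq1)
            truth.append(TruthRecord(stem, template.template_id, expected))
            ft.write(
                f"{stem}\t{template.template_id}\t"
                f"{expected if expected is not None else 'NA'}\n"
            )
    return GeneratedDataset(
        r1_path=r1_path, r2_path=r2_path, truth_path=truth_path, truth=truth
    )
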