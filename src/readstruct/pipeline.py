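"""End-to-end run orchestration: patterns → reads → segmentation → outputs.

Reads (or pairs) are processed in fixed-size chunks.  With more than one
worker the chunks are dispatched to a process pool with order-preserving
``imap``, and per-chunk results are concatenated back in input order, so
the summary table and detail file are identical for any worker count.
Segmentation is pure per-read work; only chunk granularity changes with
parallelism, never results.
"""

from __future__ import annotations

import multiprocessing
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Iterable, Iterator, Optional

from .distance import analyze_read_segments
from .io_formats import (
    RunConfig,
    detail_record,
    pair_reads,
    read_fastq,
    write_detail,
    write_summary,
)
from .patterns import (
    Diagnostic,
    PairwiseDistances,
    PatternSet,
    analyze_palindromes,
    analyze_pattern_pairs,
    check_order,
    parse_pattern_set,
)
from .search import default_max_kmer_size, segment_pair, segment_read
from .stats import StructureTable, aggregate

__all__ = ["RunResult", "load_patterns", "run_diagnostics", "run"]

CHUNK_SIZE = 512


@dataclass
class RunResult:
    pattern_set: PatternSet
    warnings: list[Diagnostic]
    pair_distances: Optional[PairwiseDistances]
    table: StructureTable
    n_units: int
    summary_html: str


def load_patterns(source: str) -> PatternSet:
    """Load patterns from a file path or an inline JSON literal.

    If ``source`` names an existing file it is read; otherwise the string
    itself is parsed as JSON.
    """
    if os.path.exists(source):
        source = Path(source).read_text()
    return parse_pattern_set(source)


def run_diagnostics(
    ps: PatternSet, confusion_threshold: int, palindrome_risk_threshold: int
) -> tuple[list[Diagnostic], PairwiseDistances]:
    """All pre-run pattern diagnostics; warnings stored on the set too."""
    warnings = check_order(ps)
    pair_warnings, dists = analyze_pattern_pairs(ps, confusion_threshold)
    warnings.extend(pair_warnings)
    warnings.extend(analyze_palindromes(ps, palindrome_risk_threshold))
    ps.warnings = warnings
    return warnings, dists


def _chunked(stream: Iterable, size: int) -> Iterator[list]:
    chunk: list = []
    for item in stream:
        chunk.append(item)
        if len(chunk) >= size:
            yield chunk
            chunk = []
    if chunk:
        yield chunk


def _process_chunk(args) -> list[tuple[str, Optional[dict]]]:
    """Segment one chunk of units; top-level so it pickles for workers."""
    chunk, ps, max_kmer, paired, want_detail, want_similarity = args
    out = []
    for unit in chunk:
        if paired:
            r1, r2 = unit
            s1, s2, structure_string = segment_pair(r1, r2, ps, max_kmer)
            reads, structs = [r1, r2], [s1, s2]
        else:
            s = segment_read(unit, ps, max_kmer)
            structure_string = s.structure_string
            reads, structs = [unit], [s]
        detail = None
        if want_detail:
            sims = (
                [analyze_read_segments(st, ps) for st in structs]
                if want_similarity
                else None
            )
            detail = detail_record(reads, structs, structure_string, sims)
        out.append((structure_string, detail))
    return out


def _units(config: RunConfig) -> Iterator:
    if config.paired:
        yield from pair_reads(
            read_fastq(config.r1_path, config.max_reads, mate="R1"),
            read_fastq(config.r2_path, config.max_reads, mate="R2"),
        )
    else:
        yield from read_fastq(config.r1_path, config.max_reads)


def run(
    config: RunConfig,
    progress: Optional[Callable[[int], None]] = None,
) -> RunResult:
    """Execute one full analysis run and write the configured outputs.

    ``progress`` (if given) is called with the number of units finished in
    each chunk — the CLI wires a tqdm bar through it.
    """
    ps = load_patterns(config.patterns_source)
    warnings, dists = run_diagnostics(
        ps, config.confusion_threshold, config.palindrome_risk_threshold
    )
    max_kmer = (
        config.max_kmer_size
        if config.max_kmer_size is not None
        else default_max_kmer_size(ps)
    )
    want_detail = config.detail_path is not None

    task_args = (
        (chunk, ps, max_kmer, config.paired, want_detail, config.read_analysis_enabled)
        for chunk in _chunked(_units(config), CHUNK_SIZE)
    )
    structures: list[str] = []
    details: list[dict] = []

    def _consume(results: Iterable[list[tuple[str, Optional[dict]]]]) -> None:
        for chunk_result in results:
            for structure_string, detail in chunk_result:
                structures.append(structure_string)
                if detail is not None:
                    details.append(detail)
            if progress is not None:
                progress(len(chunk_result))

    if config.workers > 1:
        with multiprocessing.Pool(config.workers) as pool:
            _consume(pool.imap(_process_chunk, task_args))
    else:
        _consume(map(_process_chunk, task_args))

    table = aggregate(structures)
    if want_detail:
        write_detail(details, config.detail_path)
    summary_html = write_summary(
        config, ps, warnings, dists, table, config.summary_path
    )
    return RunResult(
        pattern_set=ps,
        warnings=warnings,
        pair_distances=dists,
        table=table,
        n_units=len(structures),
        summary_html=summary_html,
    )
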