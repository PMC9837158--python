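# Methods

## Model of a read

A read is treated as a concatenation of service-sequence copies (adapters,
primers, barcodes) and everything else (insert, noise). The analyzer does
not model errors: a pattern copy either matches exactly — on the forward
strand or as its reverse complement — or it does not exist for the search.
This full-match assumption is deliberate: it keeps the output unambiguous
and fast, at the known cost that long patterns are under-counted in
error-rich data (the probability of an error-free copy decays with
length). The per-read Levenshtein analysis and the k-mer length labels are
the two compensating diagnostics.

## Segmentation procedure

Find-and-mask over a claim mask of the read:

* patterns in user dictionary order; within a pattern, forward strand then
  reverse strand; palindromic patterns are searched once, since both
  strands are the same string;
* each pattern-strand pass scans left to right, claiming every exact
  occurrence that lies entirely in unclaimed territory (greedy leftmost,
  non-overlapping within the pass — the natural semantics of sequential
  find-and-mask); an occurrence overlapping any claimed base is skipped
  whole, never partially matched;
* unclaimed maximal stretches become `{kmer:Nbp}` (N ≤ `max_kmer_size`) or
  `{unknown}` segments.

Consequences a user should understand: pattern order is a priority order
(an early short pattern can fragment the span a later long pattern needs —
hence the long-to-short ordering warning), and a forward occurrence beats
an overlapping reverse occurrence of the same pattern because its pass runs
first. Coordinates are 0-based half-open; segments tile the read exactly.

Whether both strands of pattern *i* should be processed before pattern
*i+1*, or all forward passes before all reverse passes, was an open choice;
per-pattern F-then-R was chosen as it reads most naturally as "forward
strand first, reverse strand after" for each pattern, and it keeps each
pattern's priority self-contained.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `max_kmer_size` | longest pattern + 1 (bp) | unclaimed stretches up to this length get an explicit length label; the default guarantees ±1 bp pattern variants (A-tailing, synthesis errors) are labeled rather than lumped into `{unknown}` |
| `rate_floor` | 0.001 | display-only threshold on structure rates; hidden rows are rolled into a residual line, counts and totals never change |
| `confusion_threshold` | 2 edits | pattern pairs whose minimum distance over the four strand combinations is ≤ this are flagged as confusable |
| `palindrome_risk_threshold` | 2 edits | patterns within this distance of their own reverse complement are flagged as palindrome-risk |
| `workers` | 1 | process count; results are independent of it by construction |

The two edit-distance thresholds operationalize "a few sequencing errors";
2 is one error on each of two reads of the same molecule, the smallest
value that still catches the common failure mode. Both are CLI flags.

Pattern-pair distances are reported as the minimum over all four strand
combinations (seq–seq, seq–revcomp, revcomp–seq, revcomp–revcomp), with the
per-combination values shown in the summary, because confusability in the
read is strand-blind: both strands of both patterns are searched.

## Numerical and representational choices

* Alphabet is strict A/C/G/T; IUPAC ambiguity codes are rejected with a
  clear error rather than silently never matching.
* Edit distances are computed with edlib (bit-parallel Myers algorithm);
  the test suite checks it against an independent quadratic DP oracle.
* Aggregation rows sort by count descending with lexicographic tie-break,
  so reports are byte-reproducible.
* The detail file is newline-delimited JSON inside a gzip stream — one
  object per read/pair — so it can be produced and consumed streamingly.
* FastQ compression is detected from magic bytes, not the extension;
  qualities are Phred+33 (Sanger/Illumina 1.8+); Phred+64 is out of scope.
* Reads are streamed in fixed chunks (512 units) rather than loaded whole;
  with multiple workers, chunks go through an order-preserving process
  pool, so outputs are identical for any worker count.
* R2 is searched in machine orientation, never reverse-complemented;
  orientation information is carried by the strand suffixes instead.
* Match segments are excluded from the per-read Levenshtein analysis
  (distance to their own pattern is trivially 0, to others uninformative),
  and the comparison is whole-segment vs whole-pattern — a deliberately
  coarse similarity; windowed local alignment is out of scope.

## Synthetic data generator

`readstruct.simulate` builds FastQ files from weighted structure templates:
ordered mixes of pattern tokens (strand, optional ±1 bp terminal
truncation/extension, optional point substitutions) and random filler
stretches with uniform length ranges. It emulates the layouts the analyzer
is meant to diagnose — adapter-only reads, insert-flanked barcodes,
truncated copies from A-tailing — with constant Phred 37 qualities, since
the analyzer treats qualities as pass-through data.

Truth-table exactness at zero error rate is enforced by whole-read
rejection sampling: a candidate read is accepted only when every pattern
occurrence on either strand coincides exactly with a planted intact copy.
Checking only the fillers would not suffice — occurrences can straddle
filler/pattern junctions, and a mutated copy can recreate a different
pattern. The check fails deliberately (with an error after 1,000 attempts)
for pattern sets where one pattern is a substring of another, because
nested occurrences can never be excluded; truth-labeled fixtures therefore
use non-nested pattern sets.

What the generator does **not** emulate: platform-specific error profiles
and quality decay, indels inside reads (beyond the ±1 bp terminal events),
chimeric fragments, and length distributions of real libraries. Passing
tests on generated data therefore demonstrate the correctness of the
segmentation, counting, and I/O contracts — not recall on real error-rich
data, where full-match semantics under-count long patterns by design.

## Problem sizes

The test suite and the acceptance script run on synthetic datasets of
200–1,000 reads/pairs (50–150 bp) and 10,000 random string pairs for the
distance checks — sizes at which every check is exhaustive (exact equality
on 100 % of items) while the whole suite completes in seconds. The
quantities checked are scale-free (agreement percentages, conservation
identities, determinism), so larger inputs exercise no additional logic.

## Known limitations

* No mismatch-tolerant or quality-weighted matching; no wildcards.
* No discovery of frequent unknown sequences — patterns must be specified.
* Paired mates are matched positionally (with ID validation); name-sorted
  or interleaved input is not supported.
* SAM/BAM and FASTA inputs are out of scope; FastQ only.
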