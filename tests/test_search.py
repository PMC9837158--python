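"""Segmentation engine: claiming order, strand handling, tiling, rendering."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from readstruct import ReadRecord, parse_pattern_set, segment_pair, segment_read

from conftest import make_planted_read, oracle_segment_tokens, rc


def read_of(seq: str, read_id: str = "r", mate: str = "single") -> ReadRecord:
    return ReadRecord(read_id, seq, (37,) * len(seq), mate)


class TestSegmentRead:
    def test_exact_full_read_match_forward(self, foobar_ps):
        s = segment_read(read_of("CTGTCTCTTATACAC"), foobar_ps)
        assert s.structure_string == "{foo:F}"
        (seg,) = s.segments
        assert (seg.start, seg.end, seg.pattern_name, seg.strand) == (0, 15, "foo", "F")

    def test_exact_full_read_match_reverse(self, foobar_ps):
        s = segment_read(read_of("GTGTATAAGAGACAG"), foobar_ps)
        assert s.structure_string == "{foo:R}"

    def test_flanked_match_with_kmer_and_unknown(self, foobar_ps):
        rng = random.Random(0)
        left = "".join(rng.choice("ACGT") for _ in range(60))
        right = "".join(rng.choice("ACGT") for _ in range(14))
        # default max_kmer = 16, so 60 bp -> unknown, 14 bp -> kmer
        seq = left + "CTGTCTCTTATACAC" + right
        s = segment_read(read_of(seq), foobar_ps)
        assert s.structure_string == "{unknown}{foo:F}{kmer:14bp}"

    def test_tiling_reproduces_read(self, foobar_ps):
        rng = random.Random(1)
        for _ in range(50):
            seq = make_planted_read(rng, ["CTGTCTCTTATACAC", "CCGAAAACACG", "TCGTCGGG"])
            s = segment_read(read_of(seq), foobar_ps)
            assert "".join(seg.sequence for seg in s.segments) == seq
            starts = [seg.start for seg in s.segments]
            ends = [seg.end for seg in s.segments]
            assert starts[0] == 0 and ends[-1] == len(seq)
            assert all(e == s2 for e, s2 in zip(ends, starts[1:]))

    def test_earlier_pattern_claims_overlap(self):
        # B's only occurrence overlaps A's claimed span: B must be absent
        ps = parse_pattern_set('{"a": "AAAATTTC", "b": "TTTCGGGG"}')
        seq = "AAAATTTCGGGG"  # a at [0,8); b's sole hit [4,12) overlaps it
        s = segment_read(read_of(seq), ps, max_kmer_size=4)
        assert s.structure_string == "{a:F}{kmer:4bp}"
        assert all(seg.pattern_name != "b" for seg in s.segments)

    def test_forward_strand_beats_overlapping_reverse(self):
        # p = AACCC (revcomp GGGTT); in AACCCGGGTT the F hit at 0 is claimed
        # first, then the R hit at 5 is disjoint -> both claimed F first
        ps = parse_pattern_set('{"p": "AACCC"}')
        s = segment_read(read_of("AACCCGGGTT"), ps)
        assert s.structure_string == "{p:F}{p:R}"
        # overlapping case: AACCCC contains F at 0 and would-be R of
        # GGGGTT nowhere; instead craft overlap via AAACCCGGGT with p=ACCCGG
        ps2 = parse_pattern_set('{"q": "ACCCGG"}')  # revcomp CCGGGT
        seq = "ACCCGGGT"  # F at 0 overlaps R occurrence at 2
        s2 = segment_read(read_of(seq), ps2, max_kmer_size=3)
        assert s2.segments[0].strand == "F" and s2.segments[0].start == 0

    def test_single_substitution_breaks_match(self, foobar_ps):
        seq = "CTGTCTCTTATACAG"  # foo with last base C->G
        s = segment_read(read_of(seq), foobar_ps)
        assert s.structure_string == "{kmer:15bp}"

    def test_terminal_deletion_yields_length_labeled_kmer(self, foobar_ps):
        seq = "CCGAAAACACG" + "CTGTCTCTTATACA" + "TCGTCGGG"  # foo minus last base
        s = segment_read(read_of(seq), foobar_ps)
        assert s.structure_string == "{bar:F}{kmer:14bp}{baz:F}"

    def test_kmer_vs_unknown_boundary(self, foobar_ps):
        pad16 = "T" * 16
        pad17 = "T" * 17
        assert (
            segment_read(read_of(pad16 + "TCGTCGGG"), foobar_ps).structure_string
            == "{kmer:16bp}{baz:F}"
        )
        assert (
            segment_read(read_of(pad17 + "TCGTCGGG"), foobar_ps).structure_string
            == "{unknown}{baz:F}"
        )

    def test_palindromic_pattern_rendered_without_strand(self):
        ps = parse_pattern_set('{"eco": "GAATTC", "other": "AAAA"}')
        s = segment_read(read_of("GAATTCAAAA"), ps)
        assert s.structure_string == "{eco}{other:F}"
        assert s.segments[0].strand is None

    def test_empty_read_and_empty_pattern_set_error(self, foobar_ps):
        with pytest.raises(ValueError, match="empty"):
            segment_read(read_of(""), foobar_ps)

    @settings(max_examples=100, derandomize=True)
    @given(st.text(alphabet="ACGT", min_size=1, max_size=80))
    def test_matches_bruteforce_oracle_on_random_reads(self, seq):
        pairs = [("foo", "CTGTCTCTTATACAC"), ("bar", "CCGAAAACACG"), ("baz", "TCGTCGGG")]
        ps = parse_pattern_set(
            "{" + ", ".join(f'"{n}": "{s}"' for n, s in pairs) + "}"
        )
        got = segment_read(read_of(seq), ps, max_kmer_size=16).structure_string
        assert got == oracle_segment_tokens(seq, pairs, max_kmer=16)


class TestSegmentPair:
    def test_composed_forward_reverse_pair(self, foobar_ps):
        r1 = read_of("CTGTCTCTTATACAC", "readA/1", "R1")
        r2 = read_of(rc("CTGTCTCTTATACAC"), "readA/2", "R2")
        _, _, paired = segment_pair(r1, r2, foobar_ps)
        assert paired == "R1:{foo:F} R2:{foo:R}"

    def test_all_unknown_pair(self, foobar_ps):
        rng = random.Random(3)
        mk = lambda: "".join(rng.choice("AT") for _ in range(100))
        r1, r2 = read_of(mk(), "x/1", "R1"), read_of(mk(), "x/2", "R2")
        _, _, paired = segment_pair(r1, r2, foobar_ps)
        assert paired == "R1:{unknown} R2:{unknown}"

    def test_mate_id_mismatch_names_both(self, foobar_ps):
        r1 = read_of("ACGTACGT", "readA/1", "R1")
        r2 = read_of("ACGTACGT", "readB/2", "R2")
        with pytest.raises(ValueError, match="readA.*readB"):
            segment_pair(r1, r2, foobar_ps)
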