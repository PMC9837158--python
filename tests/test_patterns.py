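"""Pattern parsing, ordering, confusability and palindrome diagnostics."""

import random

import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from readstruct import (
    PatternError,
    analyze_palindromes,
    analyze_pattern_pairs,
    check_order,
    parse_pattern_set,
    reverse_complement,
)

from conftest import dp_levenshtein, FOO_BAR_BAZ

dna = st.text(alphabet="ACGT", min_size=1, max_size=30)


class TestParse:
    def test_canonical_example_preserves_order_and_lengths(self):
        ps = parse_pattern_set(FOO_BAR_BAZ)
        assert ps.names == ["foo", "bar", "baz"]
        assert [p.length for p in ps] == [15, 11, 8]
        assert ps["foo"].revcomp == "GTGTATAAGAGACAG"

    def test_palindromic_pattern_detected(self):
        ps = parse_pattern_set('{"p": "ACGT"}')
        (p,) = ps.patterns
        assert p.revcomp == "ACGT" and p.is_palindromic

    def test_lowercase_input_canonicalized(self):
        ps = parse_pattern_set('{"x": "acgt"}')
        assert ps["x"].sequence == "ACGT"

    @pytest.mark.parametrize(
        "text, fragment",
        [
            ('{"a": "AAAN"}', "N"),  # alphabet violation names the character
            ('{"a": "A", "a": "C"}', "duplicate"),
            ("{}", "empty"),
            ('{"a": 5}', "string"),
            ('{"a": ""}', "empty"),
        ],
    )
    def test_validation_errors(self, text, fragment):
        with pytest.raises(PatternError, match=fragment):
            parse_pattern_set(text)

    def test_malformed_json_names_position(self):
        with pytest.raises(PatternError, match=r"line \d+, column \d+"):
            parse_pattern_set('{"a": "ACGT",}')


class TestOrderCheck:
    def test_long_to_short_is_silent(self, foobar_ps):
        assert check_order(foobar_ps) == []

    def test_short_before_long_warns_naming_the_pair(self):
        ps = parse_pattern_set('{"s": "TCGTCGGG", "l": "CTGTCTCTTATACAC"}')
        (w,) = check_order(ps)
        assert w.kind == "not-sorted" and w.members == ("s", "l")

    def test_equal_lengths_allowed(self):
        ps = parse_pattern_set('{"a": "AAAACCCCGG", "b": "TTTTGGGGCC", "c": "ACGT"}')
        assert check_order(ps) == []


class TestPairAnalysis:
    def test_single_substitution_pair_flagged(self):
        ps = parse_pattern_set('{"a": "ACGTACGT", "b": "ACGTACGA"}')
        warnings, dists = analyze_pattern_pairs(ps, confusion_threshold=2)
        assert dists.minimum("a", "b") == 1
        assert any(w.kind == "near-match" and w.distance == 1 for w in warnings)

    def test_substring_pattern_flagged_nested(self):
        ps = parse_pattern_set('{"long": "AACCGGTTAA", "short": "CCGGTT"}')
        warnings, _ = analyze_pattern_pairs(ps, confusion_threshold=0)
        nested = [w for w in warnings if w.kind == "nested"]
        assert len(nested) == 1 and nested[0].members == ("short", "long")

    def test_canonical_example_distances_match_dp_oracle(self, foobar_ps):
        # minima over the four strand combinations, frozen from the DP oracle
        warnings, dists = analyze_pattern_pairs(foobar_ps, confusion_threshold=2)
        assert dists.minimum("foo", "bar") == 7
        assert dists.minimum("foo", "baz") == 10
        assert dists.minimum("bar", "baz") == 7
        assert dists.by_strand[("foo", "bar")][("F", "F")] == 9
        assert not any(w.kind == "near-match" for w in warnings)

    def test_matrix_symmetric_zero_diagonal_triangle(self):
        rng = random.Random(7)
        for _ in range(25):
            seqs = {
                f"p{i}": "".join(rng.choice("ACGT") for _ in range(rng.randint(4, 20)))
                for i in range(3)
            }
            ps = parse_pattern_set(
                "{" + ", ".join(f'"{k}": "{v}"' for k, v in seqs.items()) + "}"
            )
            _, dists = analyze_pattern_pairs(ps)
            m = dists.min_matrix
            assert (m.values == m.values.T).all()
            assert (m.values.diagonal() == 0).all()
            a, b, c = ps.names
            assert m.loc[a, c] <= m.loc[a, b] + m.loc[b, c]


class TestPalindromes:
    def test_restriction_site_palindrome_flagged(self):
        (w,) = analyze_palindromes(parse_pattern_set('{"eco": "GAATTC"}'))
        assert w.kind == "palindrome"

    def test_near_palindrome_distance_two(self):
        # GAATTA vs its revcomp TAATTC: DP oracle distance 2
        (w,) = analyze_palindromes(
            parse_pattern_set('{"x": "GAATTA"}'), palindrome_risk_threshold=2
        )
        assert w.kind == "near-palindrome" and w.distance == 2

    def test_homopolymer_far_from_own_revcomp(self):
        assert analyze_palindromes(
            parse_pattern_set('{"x": "AAAAA"}'), palindrome_risk_threshold=2
        ) == []


class TestProperties:
    @settings(max_examples=200, derandomize=True)
    @given(dna)
    def test_revcomp_is_an_involution(self, s):
        assert reverse_complement(reverse_complement(s)) == s

    @settings(max_examples=200, derandomize=True)
    @given(dna.filter(lambda s: len(s) % 2 == 1))
    def test_odd_length_never_palindromic(self, s):
        ps = parse_pattern_set(f'{{"x": "{s}"}}')
        assert not ps["x"].is_palindromic
        assert all(w.kind != "palindrome" for w in analyze_palindromes(ps))

    @settings(max_examples=150, derandomize=True)
    @given(dna, dna)
    def test_pair_distances_agree_with_dp_oracle(self, a, b):
        ps = parse_pattern_set(f'{{"a": "{a}", "b": "{b}"}}')
        _, dists = analyze_pattern_pairs(ps)
        expected = min(
            dp_levenshtein(x, y)
            for x in (a, reverse_complement(a))
            for y in (b, reverse_complement(b))
        )
        assert dists.minimum("a", "b") == expected
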