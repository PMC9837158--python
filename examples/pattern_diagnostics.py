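"""Screen a pattern dictionary before running any reads.

Parses three service sequences, checks the long-to-short ordering,
computes all-pairs Levenshtein distances over strand combinations, and
flags palindromes.  Run: python examples/pattern_diagnostics.py
"""

from readstruct import (
    analyze_palindromes,
    analyze_pattern_pairs,
    check_order,
    parse_pattern_set,
)

ps = parse_pattern_set(
    '{"foo": "CTGTCTCTTATACAC", "bar": "CCGAAAACACG", "eco": "GAATTC"}'
)
print("patterns:", ", ".join(f"{p.name} ({p.length} bp)" for p in ps))

warnings = check_order(ps)
warnings_pairs, dists = analyze_pattern_pairs(ps, confusion_threshold=2)
warnings += warnings_pairs + analyze_palindromes(ps, palindrome_risk_threshold=2)

print("\npairwise minimum Levenshtein distances (over strand combinations):")
print(dists.min_matrix)

print("\nwarnings:")
for w in warnings:
    print(f"  [{w.kind}] {w.message}")

print(
    "\nA small pairwise distance means sequencing errors could interconvert "
    "two patterns; a palindrome means matches carry no strand information."
)
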