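"""Working with degenerate bracket patterns.

The P22 pseudo-pac consensus is a 17-column bracket pattern. This script
shows the pattern algebra the package provides: parsing and canonical
emission, match counting by full enumeration, column editing (the refinement
that widens column 3 from G to [GC]), diffing, and reverse complementation
for minus-strand scanning.

Run with:  python examples/04_pattern_algebra.py
"""

from pseudopac import (
    P22_PAC_SEED,
    PSEUDO_PAC_PATTERN_INITIAL,
    PSEUDO_PAC_PATTERN_REFINED,
    diff_patterns,
    edit_column,
    enumerate_sequences,
    parse_pattern,
    pattern_cardinality,
    seed_offset,
)

initial = parse_pattern(PSEUDO_PAC_PATTERN_INITIAL)
refined = parse_pattern(PSEUDO_PAC_PATTERN_REFINED)

print(f"seed      : {P22_PAC_SEED} (aligns at column "
      f"{seed_offset(initial) + 1} of both patterns)")
print(f"initial   : {initial}")
print(f"refined   : {refined}")
print()
print(f"columns            : {initial.n_columns}")
print(f"initial cardinality: {pattern_cardinality(initial):,} sequences")
print(f"refined cardinality: {pattern_cardinality(refined):,} sequences")

edits = diff_patterns(initial, refined)
print(f"columns that differ: {edits} "
      f"({''.join(sorted(initial.columns[edits[0] - 1]))} -> "
      f"{''.join(sorted(refined.columns[edits[0] - 1]))})")

rebuilt = edit_column(initial, 3, "GC")
print(f"edit_column(initial, 3, 'GC') == refined: "
      f"{rebuilt.columns == refined.columns}")

n = sum(1 for _ in enumerate_sequences(initial))
print(f"\nfull enumeration confirms the cardinality: {n:,}")

rc = refined.reverse_complement()
print(f"\nreverse complement (used for - strand scanning):")
print(f"  {rc}")
print(f"involution holds: {rc.reverse_complement().columns == refined.columns}")
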