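"""Degenerate consensus construction and bracket-pattern algebra.

Candidates found by :mod:`pseudopac.pac_search` are fixed-length, indel-free
best matches, so multiple alignment reduces to stacking the oriented
candidates (plus flanking genome sequence) with their match offsets anchored
in one column. The consensus records, per column, the set of bases observed
across rows, written in bracket notation: ``AAG[AG][TC]...`` matches any
sequence choosing one base per column.

Module constants carry the P22 system's published sequences: the 12 bp pac
seed, the 17-column pseudo-pac pattern built from the eight coverage-detected
Salmonella sites, and its refined form in which column 3 admits G or C.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

from .coverage_io import GenomeSequence, reverse_complement
from .pac_search import P22_PAC_SEED, PacCandidate

BASES = "ACGT"
_COMP = {"A": "T", "C": "G", "G": "C", "T": "A"}

#: pseudo-pac consensus built from the eight coverage-detected sites
PSEUDO_PAC_PATTERN_INITIAL = "AAG[AG][TC][AT][AT][ATC][TC][TC]T[GT][ACG][ACG][ACG]TC"
#: refined pattern: column 3 widened from G to [GC]
PSEUDO_PAC_PATTERN_REFINED = "AA[GC][AG][TC][AT][AT][ATC][TC][TC]T[GT][ACG][ACG][ACG]TC"


class PatternError(ValueError):
    """Raised for malformed bracket patterns or inconsistent consensus input."""


@dataclass(frozen=True)
class DegenerateConsensus:
    """Ordered columns of allowed bases, with an optional seed-region span."""

    columns: tuple[frozenset, ...]
    seed_span: tuple[int, int] | None = None

    def __post_init__(self):
        for i, col in enumerate(self.columns):
            if not 1 <= len(col) <= 4 or not col <= set(BASES):
                raise PatternError(f"column {i + 1}: invalid base set {set(col)}")
        if self.seed_span is not None:
            s, e = self.seed_span
            if not 0 <= s <= e <= len(self.columns):
                raise PatternError(f"seed_span {self.seed_span} out of range")

    @property
    def n_columns(self) -> int:
        return len(self.columns)

    def matches(self, seq: str) -> bool:
        """Column-wise exact match (N matches nothing)."""
        return len(seq) == self.n_columns and all(
            b in col for b, col in zip(seq, self.columns)
        )

    def reverse_complement(self) -> "DegenerateConsensus":
        cols = tuple(
            frozenset(_COMP[b] for b in col) for col in reversed(self.columns)
        )
        span = None
        if self.seed_span is not None:
            s, e = self.seed_span
            span = (self.n_columns - e, self.n_columns - s)
        return DegenerateConsensus(cols, span)

    def __str__(self) -> str:
        return emit_pattern(self)


def parse_pattern(text: str, seed_span: tuple[int, int] | None = None) -> DegenerateConsensus:
    """Parse a bracket pattern like ``AAG[AG][TC]...``.

    Whitespace between tokens is tolerated (published patterns are sometimes
    printed with line-break spaces inside them).
    """
    columns = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch.isspace():
            i += 1
        elif ch in BASES:
            columns.append(frozenset(ch))
            i += 1
        elif ch == "[":
            j = text.find("]", i)
            if j == -1:
                raise PatternError(f"unbalanced bracket at position {i}")
            group = text[i + 1 : j].replace(" ", "")
            if not group:
                raise PatternError(f"empty bracket group at position {i}")
            if set(group) - set(BASES):
                raise PatternError(f"illegal characters in group {group!r}")
            columns.append(frozenset(group))
            i = j + 1
        else:
            raise PatternError(f"illegal character {ch!r} at position {i}")
    if not columns:
        raise PatternError("empty pattern")
    return DegenerateConsensus(tuple(columns), seed_span)


def emit_pattern(c: DegenerateConsensus) -> str:
    """Canonical bracket form: singletons bare, groups in A<C<G<T order."""
    parts = []
    for col in c.columns:
        bases = "".join(b for b in BASES if b in col)
        parts.append(bases if len(bases) == 1 else f"[{bases}]")
    return "".join(parts)


def edit_column(
    c: DegenerateConsensus, position: int, new_set
) -> DegenerateConsensus:
    """Replace the base set of one column (1-based position)."""
    if not 1 <= position <= c.n_columns:
        raise PatternError(
            f"position {position} out of range 1..{c.n_columns}"
        )
    cols = list(c.columns)
    cols[position - 1] = frozenset(new_set)
    return DegenerateConsensus(tuple(cols), c.seed_span)


def pattern_cardinality(c: DegenerateConsensus) -> int:
    """Number of distinct exact sequences the pattern matches."""
    n = 1
    for col in c.columns:
        n *= len(col)
    return n


def enumerate_sequences(c: DegenerateConsensus):
    """Yield every sequence matching the pattern (test oracle)."""
    ordered = ["".join(b for b in BASES if b in col) for col in c.columns]
    for combo in itertools.product(*ordered):
        yield "".join(combo)


def diff_patterns(c1: DegenerateConsensus, c2: DegenerateConsensus) -> list[int]:
    """1-based positions whose base sets differ; patterns must be equal length."""
    if c1.n_columns != c2.n_columns:
        raise PatternError(
            f"patterns have different lengths ({c1.n_columns} vs {c2.n_columns})"
        )
    return [
        i + 1 for i, (a, b) in enumerate(zip(c1.columns, c2.columns)) if a != b
    ]


def seed_offset(pattern: DegenerateConsensus, seed: str = P22_PAC_SEED) -> int | None:
    """Smallest column offset at which the seed is column-wise compatible."""
    k = len(seed)
    for off in range(pattern.n_columns - k + 1):
        if all(b in col for b, col in zip(seed, pattern.columns[off : off + k])):
            return off
    return None


@dataclass(frozen=True)
class AlignedCandidates:
    """Equal-length oriented rows stacked with candidate starts aligned.

    ``anchor_col`` is the column where each candidate begins; the candidate
    (seed-length) region spans ``[anchor_col, anchor_col + seed_len)``.
    """

    rows: tuple[str, ...]
    anchor_col: int
    seed_len: int

    def __post_init__(self):
        if len(self.rows) < 2:
            raise PatternError("need at least 2 candidates to align")
        if len({len(r) for r in self.rows}) != 1:
            raise PatternError("aligned rows must have equal length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0])


def align_candidates(
    candidates: list[PacCandidate],
    genomes: dict[str, GenomeSequence] | GenomeSequence,
    flank: int = 20,
) -> AlignedCandidates:
    """Stack oriented candidates extended by ``flank`` bp of genome context.

    Rows read 5'->3' on the packaging strand. Flanks running past a genome
    end are padded with N so all rows keep the same length; candidates are
    ungapped best-match hits of one fixed length, so no gaps are introduced.
    """
    if len(candidates) < 2:
        raise PatternError("need at least 2 candidates to build a consensus")
    if isinstance(genomes, GenomeSequence):
        genomes = {genomes.id: genomes}
    seed_len = len(candidates[0].seq)
    rows = []
    for c in candidates:
        if c.end - c.start != seed_len:
            raise PatternError("candidates have inconsistent lengths")
        genome = genomes[c.site.genome_id]
        lo, hi = c.start - flank, c.end + flank
        left_pad = "N" * max(0, -lo)
        right_pad = "N" * max(0, hi - genome.length)
        row = left_pad + genome.seq[max(lo, 0) : min(hi, genome.length)] + right_pad
        if c.strand == "-":
            row = reverse_complement(row)
        rows.append(row)
    return AlignedCandidates(tuple(rows), anchor_col=flank, seed_len=seed_len)


def _column_set(column_bases: list[str], min_rows_fraction: float) -> frozenset:
    """Smallest most-frequent-first base set covering the required row fraction.

    At the default fraction 1.0 this is exactly the set of bases observed
    (N ignored); below 1.0 rare bases are dropped once the frequent ones
    cover enough rows.
    """
    observed = [b for b in column_bases if b != "N"]
    if not observed:
        return frozenset()
    counts = {b: observed.count(b) for b in set(observed)}
    need = min_rows_fraction * len(observed)
    chosen, covered = [], 0
    for b in sorted(counts, key=lambda b: (-counts[b], b)):
        chosen.append(b)
        covered += counts[b]
        if covered >= need:
            break
    return frozenset(chosen)


def build_consensus(
    aligned: AlignedCandidates,
    max_variants: int = 3,
    min_rows_fraction: float = 1.0,
) -> DegenerateConsensus:
    """Build the degenerate consensus from aligned rows.

    A column is conserved iff its base set has at most ``max_variants``
    members (and at least one non-N observation); the consensus is the
    maximal contiguous run of conserved columns containing the anchored
    seed region, with that region recorded as ``seed_span``.
    """
    n_cols = aligned.n_columns
    sets = [
        _column_set([row[i] for row in aligned.rows], min_rows_fraction)
        for i in range(n_cols)
    ]
    conserved = [1 <= len(s) <= max_variants for s in sets]
    seed_start = aligned.anchor_col
    seed_end = seed_start + aligned.seed_len
    if not all(conserved[seed_start:seed_end]):
        raise PatternError(
            "no conserved run covers the seed region "
            f"(columns {seed_start}..{seed_end})"
        )
    run_start = seed_start
    while run_start > 0 and conserved[run_start - 1]:
        run_start -= 1
    run_end = seed_end
    while run_end < n_cols and conserved[run_end]:
        run_end += 1
    return DegenerateConsensus(
        tuple(sets[run_start:run_end]),
        seed_span=(seed_start - run_start, seed_end - run_start),
    )
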