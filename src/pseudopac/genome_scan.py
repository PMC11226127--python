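"""Dual-strand scanning of genomes for degenerate consensus matches.

Matching is implemented directly over column base sets rather than through a
regular-expression engine: the reverse strand is scanned by matching the
forward string against the reverse-complemented pattern, which makes strand
behavior provably symmetric. N in the genome matches no column. Overlapping
matches, and both records of a palindromic hit, are all reported.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .consensus import DegenerateConsensus
from .coverage_io import GenomeSequence, reverse_complement

_CODE = np.full(256, 4, dtype=np.uint8)
for _i, _b in enumerate("ACGT"):
    _CODE[ord(_b)] = _i


@dataclass(frozen=True)
class PatternMatch:
    """A pattern hit reported in forward-strand coordinates.

    ``matched_seq`` reads 5'->3' on the match strand: for - matches it is the
    reverse complement of the forward-strand slice ``[start, end)``.
    """

    genome_id: str
    start: int
    end: int
    strand: str
    matched_seq: str


def _encode(seq: str) -> np.ndarray:
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def _forward_hits(encoded: np.ndarray, c: DegenerateConsensus) -> np.ndarray:
    """Start positions where the pattern matches the encoded forward string."""
    k = c.n_columns
    n = len(encoded)
    if n < k:
        return np.empty(0, dtype=int)
    valid = np.ones(n - k + 1, dtype=bool)
    for j, col in enumerate(c.columns):
        allowed = np.zeros(5, dtype=bool)
        for b in col:
            allowed["ACGT".index(b)] = True
        valid &= allowed[encoded[j : n - k + 1 + j]]
    return np.flatnonzero(valid)


def scan_genome(
    genome: GenomeSequence, c: DegenerateConsensus
) -> list[PatternMatch]:
    """All matches on both strands, sorted by start (+ before - at ties)."""
    k = c.n_columns
    if genome.length < k:
        raise ValueError(
            f"pattern ({k} columns) longer than genome {genome.id!r} "
            f"({genome.length} bp)"
        )
    encoded = _encode(genome.seq)
    matches = []
    for strand, pattern in (("+", c), ("-", c.reverse_complement())):
        for start in _forward_hits(encoded, pattern):
            start = int(start)
            seq = genome.seq[start : start + k]
            if strand == "-":
                seq = reverse_complement(seq)
            matches.append(
                PatternMatch(genome.id, start, start + k, strand, seq)
            )
    return sorted(matches, key=lambda m: (m.start, m.strand != "+"))


def count_matches(
    genome: GenomeSequence, c: DegenerateConsensus
) -> tuple[int, int, int]:
    """(total, forward, reverse) match counts."""
    matches = scan_genome(genome, c)
    n_fwd = sum(1 for m in matches if m.strand == "+")
    return len(matches), n_fwd, len(matches) - n_fwd


def write_matches_bed(matches: list[PatternMatch], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, m in enumerate(matches, 1):
            fh.write(
                f"{m.genome_id}\t{m.start}\t{m.end}\t"
                f"match_{i}\t1000\t{m.strand}\n"
            )


def read_matches_bed(path: str | Path, genome: GenomeSequence) -> list[PatternMatch]:
    """Rebuild matches (with sequences) from BED plus the genome."""
    matches = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, _name, _score, strand = line.split("\t")[:6]
            start, end, strand = int(start), int(end), strand.strip()
            seq = genome.seq[start:end]
            if strand == "-":
                seq = reverse_complement(seq)
            matches.append(PatternMatch(chrom, start, end, strand, seq))
    return matches
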