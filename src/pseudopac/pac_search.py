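"""Best-match search for pac-like sequences around initiation sites.

The packaging machinery cuts within a ~120 bp region surrounding its
recognition (pac) site, so each detected initiation site is expanded into a
window of that size, oriented 5'->3' on the packaging strand, and searched
for the substring with the smallest Hamming distance to the seed pac
consensus (the 12-mer recognized by the P22 small terminase by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

from .coverage_io import GenomeSequence, reverse_complement
from .site_detection import InitiationSite

#: 12 bp P22 pac consensus recognized by the small terminase
P22_PAC_SEED = "AAGATTTATCTG"


@dataclass(frozen=True)
class SearchParams:
    window_len: int = 120
    seed: str = P22_PAC_SEED

    def __post_init__(self):
        if not 0 < len(self.seed) <= self.window_len:
            raise ValueError("need window_len >= len(seed) > 0")


@dataclass(frozen=True)
class WindowExtract:
    """An oriented window with its forward-strand extent.

    ``seq`` reads 5'->3' on the packaging strand: the forward-strand slice
    ``[fwd_start, fwd_end)`` for + sites, its reverse complement for - sites.
    """

    seq: str
    fwd_start: int
    fwd_end: int
    strand: str

    def to_forward(self, offset: int, length: int) -> tuple[int, int]:
        """Map a window-coordinate slice back to forward-strand coordinates."""
        if self.strand == "+":
            return self.fwd_start + offset, self.fwd_start + offset + length
        return self.fwd_end - offset - length, self.fwd_end - offset


@dataclass(frozen=True)
class PacCandidate:
    """Best seed match in the window around one initiation site."""

    site: InitiationSite
    seq: str
    start: int
    end: int
    strand: str
    mismatches: int


def extract_window(
    genome: GenomeSequence, site: InitiationSite, window_len: int = 120
) -> WindowExtract:
    """Extract the oriented window centered on the site position.

    Windows running past a genome end are clamped with a warning; a genome
    shorter than the window is an error.
    """
    if genome.length < window_len:
        raise ValueError(
            f"genome {genome.id!r} ({genome.length} bp) shorter than the "
            f"{window_len} bp window"
        )
    half = window_len // 2
    start = site.position - half
    end = start + window_len
    if start < 0 or end > genome.length:
        warnings.warn(
            f"window around position {site.position} clamped to genome "
            f"{genome.id!r} bounds",
            stacklevel=2,
        )
        start = max(start, 0)
        end = min(end, genome.length)
    seq = genome.seq[start:end]
    if site.strand == "-":
        seq = reverse_complement(seq)
    return WindowExtract(seq, start, end, site.strand)


def hamming(a: str, b: str) -> int:
    """Mismatch count between equal-length strings; N never matches."""
    if len(a) != len(b):
        raise ValueError("sequences must have equal length")
    return sum(1 for x, y in zip(a, b) if x != y or x == "N")


def best_match(window: str, seed: str) -> tuple[int, str, int]:
    """Offset, substring and mismatch count of the best seed match.

    Minimizes Hamming distance over all offsets; ties go to the smallest
    offset. N in either sequence counts as a mismatch.
    """
    k = len(seed)
    if len(window) < k:
        raise ValueError("window shorter than seed")
    best_off, best_d = 0, k + 1
    for off in range(len(window) - k + 1):
        d = hamming(window[off : off + k], seed)
        if d < best_d:
            best_off, best_d = off, d
    return best_off, window[best_off : best_off + k], best_d


def find_candidates(
    genome: GenomeSequence,
    sites: list[InitiationSite],
    params: SearchParams | None = None,
) -> list[PacCandidate]:
    """One :class:`PacCandidate` per site: extract window, find best match."""
    params = params or SearchParams()
    candidates = []
    for site in sites:
        window = extract_window(genome, site, params.window_len)
        offset, matched, mismatches = best_match(window.seq, params.seed)
        start, end = window.to_forward(offset, len(params.seed))
        candidates.append(
            PacCandidate(
                site=site,
                seq=matched,
                start=start,
                end=end,
                strand=site.strand,
                mismatches=mismatches,
            )
        )
    return candidates


def write_candidates_bed(candidates: list[PacCandidate], path: str | Path) -> None:
    with open(path, "w") as fh:
        for i, c in enumerate(candidates, 1):
            score = max(0, 1000 - 100 * c.mismatches)
            fh.write(
                f"{c.site.genome_id}\t{c.start}\t{c.end}\t"
                f"cand_{i};mm={c.mismatches}\t{score}\t{c.strand}\n"
            )


def write_candidates_fasta(candidates: list[PacCandidate], path: str | Path) -> None:
    """Oriented candidate sequences; headers carry site number, strand, mismatches."""
    with open(path, "w") as fh:
        for i, c in enumerate(candidates, 1):
            fh.write(
                f">cand_{i} strand={c.strand} mismatches={c.mismatches} "
                f"loc={c.start}-{c.end}\n{c.seq}\n"
            )


def read_candidates_bed(path: str | Path) -> list[tuple[str, int, int, str]]:
    """(genome_id, start, end, strand) tuples from a candidates BED file."""
    out = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, end, _name, _score, strand = line.split("\t")[:6]
            out.append((chrom, int(start), int(end), strand.strip()))
    return out
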