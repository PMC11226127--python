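"""Genome and read-depth input/output.

Genomes are plain uppercase A/C/G/T/N sequences read from FASTA. Read depth
comes either as a per-base TSV (chrom, 1-based position, depth) or as a
bedGraph (chrom, 0-based half-open start/end, value) and is reduced to a
:class:`CoverageTrack` of per-bin mean depths. All internal coordinates are
0-based, half-open; 1-based coordinates appear only at file boundaries.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from Bio import SeqIO

VALID_BASES = frozenset("ACGTN")
_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

DEFAULT_BINSIZE = 25


class FormatError(ValueError):
    """Raised for malformed FASTA or depth files."""


def reverse_complement(seq: str) -> str:
    """Reverse complement of a nucleotide string (N stays N)."""
    seq = seq.upper()
    bad = set(seq) - VALID_BASES
    if bad:
        raise FormatError(f"illegal characters in sequence: {sorted(bad)}")
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class GenomeSequence:
    """A named nucleotide sequence over {A,C,G,T,N}."""

    id: str
    seq: str

    def __post_init__(self):
        object.__setattr__(self, "seq", self.seq.upper())
        if len(self.seq) == 0:
            raise FormatError(f"record {self.id!r}: empty sequence")
        bad = set(self.seq) - VALID_BASES
        if bad:
            raise FormatError(
                f"record {self.id!r}: illegal characters {sorted(bad)}"
            )

    @property
    def length(self) -> int:
        return len(self.seq)

    def reverse_complement(self) -> "GenomeSequence":
        return GenomeSequence(self.id, reverse_complement(self.seq))


@dataclass
class CoverageTrack:
    """Binned mean read depth across one genome.

    ``values[i]`` is the mean depth over bases
    ``[i*binsize, min((i+1)*binsize, genome_length))``; the final bin may be
    partial and is averaged over its actual width.
    """

    genome_id: str
    binsize: int
    values: np.ndarray
    genome_length: int

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.binsize < 1:
            raise ValueError("binsize must be >= 1")
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        expected = -(-self.genome_length // self.binsize)
        if len(self.values) != expected:
            raise ValueError(
                f"expected {expected} bins for genome_length "
                f"{self.genome_length} at binsize {self.binsize}, "
                f"got {len(self.values)}"
            )
        if not np.all(np.isfinite(self.values)) or np.any(self.values < 0):
            raise ValueError("coverage values must be finite and >= 0")

    @property
    def n_bins(self) -> int:
        return len(self.values)

    def bin_widths(self) -> np.ndarray:
        widths = np.full(self.n_bins, self.binsize, dtype=int)
        rem = self.genome_length - (self.n_bins - 1) * self.binsize
        widths[-1] = rem
        return widths

    def total_depth(self) -> float:
        """Sum of per-base depth represented by the track."""
        return float(np.dot(self.values, self.bin_widths()))

    def reversed(self) -> "CoverageTrack":
        """Bin-level mirror image (genome_length must be a bin multiple)."""
        if self.genome_length % self.binsize != 0:
            raise ValueError(
                "cannot mirror a track with a partial final bin"
            )
        return CoverageTrack(
            self.genome_id, self.binsize, self.values[::-1].copy(),
            self.genome_length,
        )


def read_fasta(path: str | Path) -> list[GenomeSequence]:
    """Read genomes from a FASTA file, validating the alphabet."""
    path = Path(path)
    text_head = path.read_text()[:1] if path.stat().st_size else ""
    if text_head == "":
        raise FormatError(f"{path}: empty FASTA file")
    if text_head != ">":
        raise FormatError(f"{path}: malformed header (file must start with '>')")
    genomes = []
    for rec in SeqIO.parse(str(path), "fasta"):
        if not rec.id:
            raise FormatError(f"{path}: record with empty header")
        genomes.append(GenomeSequence(rec.id, str(rec.seq)))
    if not genomes:
        raise FormatError(f"{path}: no FASTA records")
    return genomes


def _detect_dialect(fields_per_line: list[int]) -> str:
    if all(n >= 4 for n in fields_per_line):
        return "bedgraph"
    return "perbase"


def read_depth(
    path: str | Path,
    binsize: int = DEFAULT_BINSIZE,
    genome_length: int | None = None,
    genome_id: str | None = None,
    dialect: str = "auto",
) -> CoverageTrack:
    """Read a depth file and bin it into a :class:`CoverageTrack`.

    Parameters
    ----------
    path
        Per-base TSV (chrom, 1-based pos, depth) or bedGraph
        (chrom, 0-based start, end, value); auto-detected by column count
        unless ``dialect`` is ``"perbase"`` or ``"bedgraph"``.
    genome_length
        Declared genome length; inferred from the largest covered position
        when omitted. Positions beyond a declared length are an error.
    genome_id
        Select one chromosome from the file. When omitted the file must
        contain a single chromosome.

    Positions absent from the file count as depth 0.
    """
    path = Path(path)
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            line = line.strip()
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t") if "\t" in line else line.split()
            rows.append((lineno, fields))
    if dialect == "auto":
        dialect = _detect_dialect([len(f) for _, f in rows]) if rows else "perbase"
    if dialect not in ("perbase", "bedgraph"):
        raise ValueError(f"unknown depth dialect {dialect!r}")

    intervals = []  # (start, end, value), 0-based half-open
    chroms = set()
    for lineno, fields in rows:
        try:
            if dialect == "perbase":
                chrom, pos, depth = fields[0], int(fields[1]), float(fields[2])
                if pos < 1:
                    raise ValueError("position must be >= 1")
                start, end = pos - 1, pos
            else:
                chrom = fields[0]
                start, end = int(fields[1]), int(fields[2])
                depth = float(fields[3])
                if not (0 <= start < end):
                    raise ValueError("need 0 <= start < end")
        except (IndexError, ValueError) as exc:
            raise FormatError(f"{path}:{lineno}: bad depth record: {exc}") from exc
        if not np.isfinite(depth) or depth < 0:
            raise FormatError(f"{path}:{lineno}: non-finite or negative depth")
        if genome_id is not None and chrom != genome_id:
            continue
        chroms.add(chrom)
        intervals.append((start, end, depth))

    if len(chroms) > 1:
        raise FormatError(
            f"{path}: depth file mixes chromosomes {sorted(chroms)}; "
            "pass genome_id to select one"
        )
    if genome_id is None:
        genome_id = next(iter(chroms)) if chroms else "unknown"

    max_end = max((e for _, e, _ in intervals), default=0)
    if genome_length is None:
        genome_length = max_end if max_end else binsize
    elif max_end > genome_length:
        raise FormatError(
            f"{path}: position {max_end} beyond declared genome length "
            f"{genome_length}"
        )

    n_bins = -(-genome_length // binsize)
    widths = np.full(n_bins, binsize, dtype=int)
    widths[-1] = genome_length - (n_bins - 1) * binsize
    sums = np.zeros(n_bins, dtype=float)
    # contributions from intervals exactly covering whole bins enter the mean
    # directly (depth * width / width cancels algebraically but not in floats,
    # and re-reading our own bedGraph must reproduce values exactly)
    means = np.zeros(n_bins, dtype=float)
    for start, end, depth in intervals:
        b0, b1 = start // binsize, (end - 1) // binsize
        for b in range(b0, b1 + 1):
            lo = max(start, b * binsize)
            hi = min(end, b * binsize + int(widths[b]))
            if hi - lo == widths[b]:
                means[b] += depth
            else:
                sums[b] += depth * (hi - lo)
    return CoverageTrack(genome_id, binsize, means + sums / widths, genome_length)


def write_bedgraph(track: CoverageTrack, path: str | Path) -> None:
    """Write a track as bedGraph, one line per bin."""
    widths = track.bin_widths()
    with open(path, "w") as fh:
        pos = 0
        for value, width in zip(track.values, widths):
            fh.write(f"{track.genome_id}\t{pos}\t{pos + width}\t{float(value)!r}\n")
            pos += width


def write_fasta(genomes: list[GenomeSequence], path: str | Path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for g in genomes:
            fh.write(f">{g.id}\n")
            for i in range(0, g.length, width):
                fh.write(g.seq[i : i + width] + "\n")
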