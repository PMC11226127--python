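"""Detection of packaging-initiation sites from coverage tracks.

A headful-packaging initiation site shows up in phage-read coverage mapped to
the host genome as a sudden sharp jump followed by a long, strand-directional,
stair-like decay (one stair tread per headful). Detection replaces the visual
call with three per-boundary statistics:

* jump ratio ``D / (U + eps)`` between the mean depth of ``flank_bins`` bins
  downstream (``D``, in the packaging direction) and upstream (``U``),
* absolute jump ``D - U``,
* decay fraction: the fraction of adjacent bin pairs that are non-increasing
  over the next ``decay_span_bins`` bins in the packaging direction.

On stair-like decay the treads between headful boundaries are flat, so the
decay fraction concentrates near 1/2 (noise makes adjacent flat bins a coin
flip) whatever the decay rate; the default threshold therefore sits just
below 1/2 and rejects only windows dominated by fine-scale increases, while
the two jump statistics carry the detection. Minus-strand sites are found by
running the identical computation on the reversed track, which makes
detection exactly mirror-equivariant.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .coverage_io import CoverageTrack

#: added to the upstream mean in the jump ratio to tolerate zero background
RATIO_EPSILON = 0.5


@dataclass(frozen=True)
class DetectionParams:
    """Thresholds operationalizing "sharp jump followed by decay".

    Defaults are calibrated on the packaging simulator at its default
    conditions (see docs/methods.md), where overlapping packaging series from
    neighboring sites raise the local baseline: true sites keep jump ratios
    near or above 2 while headful stair steps stay below ~1.4.
    """

    flank_bins: int = 20
    min_jump_ratio: float = 1.6
    min_abs_jump: float = 5.0
    decay_span_bins: int = 3440
    min_decay_fraction: float = 0.45
    min_separation: int = 50_000

    def __post_init__(self):
        if self.flank_bins < 1 or self.decay_span_bins < 1:
            raise ValueError("flank_bins and decay_span_bins must be >= 1")
        if self.min_jump_ratio < 1:
            raise ValueError("min_jump_ratio must be >= 1")
        if not 0 <= self.min_decay_fraction <= 1:
            raise ValueError("min_decay_fraction must be in [0, 1]")
        if self.min_separation < 0:
            raise ValueError("min_separation must be >= 0")


@dataclass(frozen=True)
class InitiationSite:
    """A detected coverage jump.

    ``position`` is the 0-based bp coordinate of the jump boundary. Strand
    ``+`` means coverage steps up at the position and decays with increasing
    coordinate (packaging proceeds rightward); ``-`` is the mirror image.
    """

    genome_id: str
    position: int
    strand: str
    jump_ratio: float
    decay_fraction: float
    abs_jump: float = 0.0


def boundary_statistics(
    values: np.ndarray, boundary: int, strand: str, params: DetectionParams
) -> tuple[float, float, float]:
    """(jump_ratio, abs_jump, decay_fraction) at one bin boundary.

    The boundary indexes between bins ``boundary - 1`` and ``boundary``.
    Flank windows are clamped at the track ends; the decay window is taken in
    the packaging direction and clamped at the track end.
    """
    v = values if strand == "+" else values[::-1]
    b = boundary if strand == "+" else len(values) - boundary
    f = params.flank_bins
    lo = max(b - f, 0)
    hi = min(b + f, len(v))
    if b - lo == 0 or hi - b == 0:
        raise ValueError("boundary has no flank on one side")
    upstream = float(v[lo:b].mean())
    downstream = float(v[b:hi].mean())
    end = min(b + params.decay_span_bins, len(v))
    window = v[b:end]
    if len(window) > 1:
        decay = float(np.mean(window[1:] <= window[:-1]))
    else:
        decay = 1.0
    ratio = downstream / (upstream + RATIO_EPSILON)
    return ratio, downstream - upstream, decay


def _oriented_calls(
    values: np.ndarray, params: DetectionParams, binsize: int, genome_id: str,
    strand: str,
) -> list[InitiationSite]:
    """All boundaries passing the gates for one packaging direction."""
    v = values if strand == "+" else values[::-1]
    n = len(v)
    f = params.flank_bins
    cum = np.concatenate(([0.0], np.cumsum(v)))
    b = np.arange(f, n - f + 1)
    upstream = (cum[b] - cum[b - f]) / f
    downstream = (cum[b + f] - cum[b]) / f
    ratio = downstream / (upstream + RATIO_EPSILON)
    jump = downstream - upstream
    cand = b[(ratio >= params.min_jump_ratio) & (jump >= params.min_abs_jump)]
    # non-increasing adjacent-pair fraction over the (clamped) decay window
    noninc = np.concatenate(([0.0], np.cumsum(v[1:] <= v[:-1])))
    calls = []
    for bi in cand:
        end = min(bi + params.decay_span_bins, n)
        n_pairs = end - bi - 1
        decay = (noninc[end - 1] - noninc[bi]) / n_pairs if n_pairs > 0 else 1.0
        if decay < params.min_decay_fraction:
            continue
        boundary = bi if strand == "+" else n - bi
        i = bi - f
        calls.append(
            InitiationSite(
                genome_id=genome_id,
                position=int(boundary) * binsize,
                strand=strand,
                jump_ratio=float(ratio[i]),
                decay_fraction=float(decay),
                abs_jump=float(jump[i]),
            )
        )
    return calls


def _cluster(calls: list[InitiationSite], min_separation: int) -> list[InitiationSite]:
    """Greedy non-maximum suppression within ``min_separation`` bp.

    Best call first (highest absolute jump, then highest ratio, then
    leftmost), suppressing everything within the separation window. The
    absolute jump peaks at the center of the initiation ramp, whereas the
    ratio peaks upstream of it (where the upstream flank clears the ramp),
    so ranking by absolute jump localizes the boundary.
    """
    order = sorted(calls, key=lambda s: (-s.abs_jump, -s.jump_ratio, s.position))
    kept: list[InitiationSite] = []
    for call in order:
        if all(abs(call.position - k.position) >= min_separation for k in kept):
            kept.append(call)
    return sorted(kept, key=lambda s: s.position)


def detect_initiation_sites(
    track: CoverageTrack, params: DetectionParams | None = None
) -> list[InitiationSite]:
    """Detect initiation sites on both strands of a coverage track."""
    params = params or DetectionParams()
    if track.n_bins < 2 * params.flank_bins + 1:
        raise ValueError(
            f"track has {track.n_bins} bins; need at least "
            f"{2 * params.flank_bins + 1} for flank windows of "
            f"{params.flank_bins} bins"
        )
    calls = _oriented_calls(track.values, params, track.binsize, track.genome_id, "+")
    calls += _oriented_calls(track.values, params, track.binsize, track.genome_id, "-")
    calls = [c for c in calls if 0 <= c.position < track.genome_length]
    return _cluster(calls, params.min_separation)


def write_sites_bed(sites: list[InitiationSite], path: str | Path) -> None:
    """BED6 output: one 1-bp feature per site, score = min(1000, 100*ratio)."""
    with open(path, "w") as fh:
        for i, s in enumerate(sites, 1):
            score = min(1000, round(100 * s.jump_ratio))
            fh.write(
                f"{s.genome_id}\t{s.position}\t{s.position + 1}\t"
                f"site_{i}\t{score}\t{s.strand}\n"
            )


def read_sites_bed(path: str | Path) -> list[InitiationSite]:
    """Read sites back from :func:`write_sites_bed` output."""
    sites = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, _end, _name, score, strand = line.split("\t")[:6]
            sites.append(
                InitiationSite(
                    genome_id=chrom,
                    position=int(start),
                    strand=strand.strip(),
                    jump_ratio=float(score) / 100.0,
                    decay_fraction=float("nan"),
                )
            )
    return sites
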