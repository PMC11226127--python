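"""Synthetic genomes and headful-packaging coverage with planted ground truth.

The generator emulates the coverage phenomenology of phage reads mapped to a
host genome when packaging initiates at planted pac-like sites: each
initiation event packages a series of fixed-length headfuls processively
along the packaging direction, so depth jumps sharply at the site and decays
as a staircase (one tread per headful) over hundreds of kb, on top of a low
uniform Poisson background. Series length is geometric (memoryless series
termination), capped so tail probabilities below the cap keep the closed form
``P(L >= m) = (1 - 1/mean)^(m-1)`` used as a coverage oracle.

Ground truth (planted positions, strands, sequences and the jump boundary)
is returned for every pipeline stage. By default the generator guarantees
*identifiability*: the planted seed-region 12-mer is the strict best Hamming
match to the pac seed within the region any extraction window can reach, so
"the candidate equals the planted sequence" is well defined. Without this, a
uniform draw from the degenerate pattern sits ~4 mismatches from the seed and
a ~120 bp window of random sequence ties or beats it often enough to make the
planted truth ambiguous.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .consensus import (
    DegenerateConsensus,
    PSEUDO_PAC_PATTERN_REFINED,
    parse_pattern,
    seed_offset,
)
from .coverage_io import CoverageTrack, GenomeSequence, reverse_complement
from .pac_search import P22_PAC_SEED, hamming
from .site_detection import DetectionParams, detect_initiation_sites
from . import pac_search, genome_scan, evidence as evidence_mod
from .consensus import align_candidates, build_consensus, PatternError

_BYTES = np.frombuffer(b"ACGT", dtype=np.uint8)


def default_site_pattern() -> DegenerateConsensus:
    return parse_pattern(PSEUDO_PAC_PATTERN_REFINED)


@dataclass
class SimulationConfig:
    """Study conditions for one simulated packaging experiment.

    ``headful`` defaults to a plausible P22-scale capsid capacity; the
    ±``cut_jitter`` initiation scatter matches the ~120 bp cut region around
    the pac site. Site placement is an evenly spaced grid with ±10 kb jitter
    by default (``placement="random"`` draws positions uniformly subject to
    the 2-headful separation), or explicit via ``site_positions``.
    """

    genome_length: int = 2_000_000
    n_sites: int = 8
    site_pattern: DegenerateConsensus = field(default_factory=default_site_pattern)
    strand_assignment: str | list[str] = "random"
    headful: int = 43_000
    series_mean: float = 5.0
    series_max: int = 12
    events_per_site: int = 200
    cut_jitter: int = 60
    background_rate: float = 1.0
    binsize: int = 25
    seed: int = 0
    genome_id: str = "sim"
    seed_sequence: str = P22_PAC_SEED
    ensure_identifiable: bool = True
    placement: str = "even"
    placement_jitter: int = 10_000
    site_positions: list[int] | None = None

    def __post_init__(self):
        if self.headful <= 0:
            raise ValueError("headful must be > 0")
        if self.series_mean < 1:
            raise ValueError("series_mean must be >= 1")
        if self.series_max < 1:
            raise ValueError("series_max must be >= 1")
        if self.genome_length < 1:
            raise ValueError("genome_length must be >= 1")
        if self.cut_jitter < 0 or self.events_per_site < 0 or self.n_sites < 0:
            raise ValueError("counts must be >= 0")
        if self.background_rate < 0:
            raise ValueError("background_rate must be >= 0")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


@dataclass(frozen=True)
class PlantedSite:
    """Ground truth for one planted site.

    ``position`` is the forward-strand start of the implanted pattern draw;
    ``sequence`` reads 5'->3' on the packaging strand. ``boundary`` is the bp
    coordinate where coverage jumps (the oriented start of the seed region);
    ``seed_start``/``seed_end`` delimit the seed-region 12-mer on the forward
    strand.
    """

    genome_id: str
    position: int
    strand: str
    sequence: str
    boundary: int
    seed_start: int
    seed_end: int


def draw_site_sequence(pattern: DegenerateConsensus, rng: np.random.Generator) -> str:
    """One base drawn uniformly per column; always matches the pattern."""
    out = []
    for col in pattern.columns:
        options = sorted(col)
        out.append(options[int(rng.integers(len(options)))])
    return "".join(out)


def _place_sites(config: SimulationConfig, rng: np.random.Generator) -> list[int]:
    n, L = config.n_sites, config.genome_length
    if config.site_positions is not None:
        positions = list(config.site_positions)
        if len(positions) != n:
            raise ValueError("site_positions length must equal n_sites")
        return positions
    if n == 0:
        return []
    min_sep = 2 * config.headful
    if config.placement == "even":
        spacing = L / n
        if spacing < min_sep + 2 * config.placement_jitter:
            raise ValueError(
                "sites cannot be placed with required separation "
                f"(need >= {min_sep} bp between {n} sites in {L} bp)"
            )
        jit = config.placement_jitter
        return [
            int((k + 0.5) * spacing) + int(rng.integers(-jit, jit + 1))
            for k in range(n)
        ]
    if config.placement == "random":
        margin = min(config.headful, L // 10)
        for _ in range(500):
            pos = np.sort(rng.integers(margin, max(L - margin, margin + 1), n))
            if n == 1 or np.all(np.diff(pos) >= min_sep):
                return [int(p) for p in pos]
        raise ValueError("sites cannot be placed with required separation")
    raise ValueError(f"unknown placement {config.placement!r}")


def _enforce_identifiability(
    codes: np.ndarray,
    site: PlantedSite,
    pattern: DegenerateConsensus,
    seed: str,
    so: int,
    rng: np.random.Generator,
    window_len: int = 120,
) -> str:
    """Make the planted seed-region 12-mer the strict best seed match nearby.

    The reachable region covers every offset an extraction window centered
    within the cut-jitter scatter of the boundary can contain. Background
    bases in the region are redrawn while any competing offset ties or beats
    the planted one; if the conflict lies inside the implant itself the
    implant is redrawn.
    """
    L = len(codes)
    k = len(seed)
    patlen = pattern.n_columns
    target = seed if site.strand == "+" else reverse_complement(seed)
    lo = max(site.boundary - window_len, 0)
    hi = min(site.boundary + window_len, L)
    implant = (site.position, site.position + patlen)
    sequence = site.sequence
    for attempt in range(400):
        region = bytes(_BYTES[codes[lo:hi]]).decode()
        planted_off = site.seed_start - lo
        d_star = hamming(region[planted_off : planted_off + k], target)
        conflict = None
        for off in range(len(region) - k + 1):
            if off == planted_off:
                continue
            if hamming(region[off : off + k], target) <= d_star:
                conflict = off
                break
        if conflict is None:
            return sequence
        conflict_span = (lo + conflict, lo + conflict + k)
        inside_implant = (
            conflict_span[0] >= implant[0] and conflict_span[1] <= implant[1]
        )
        if inside_implant or attempt % 25 == 24:
            sequence = draw_site_sequence(pattern, rng)
            implanted = sequence if site.strand == "+" else reverse_complement(sequence)
            codes[implant[0] : implant[1]] = [
                "ACGT".index(b) for b in implanted
            ]
        else:
            for i in range(lo, hi):
                if not implant[0] <= i < implant[1]:
                    codes[i] = rng.integers(4)
    raise RuntimeError("could not make a planted site identifiable")


def simulate_genome(
    config: SimulationConfig, rng: np.random.Generator | None = None
) -> tuple[GenomeSequence, list[PlantedSite]]:
    """I.i.d. uniform background with pattern draws implanted at placed sites."""
    rng = rng if rng is not None else config.rng()
    L = config.genome_length
    pattern = config.site_pattern
    patlen = pattern.n_columns
    codes = rng.integers(0, 4, L, dtype=np.uint8)
    positions = _place_sites(config, rng)
    if isinstance(config.strand_assignment, str):
        if config.strand_assignment == "random":
            strands = [
                "+" if rng.integers(2) == 0 else "-" for _ in positions
            ]
        else:
            strands = [config.strand_assignment] * len(positions)
    else:
        strands = list(config.strand_assignment)
        if len(strands) != len(positions):
            raise ValueError("strand_assignment length must equal n_sites")
    so = seed_offset(pattern, config.seed_sequence)
    k = len(config.seed_sequence)
    truth = []
    for pos, strand in zip(positions, strands):
        if not 0 <= pos <= L - patlen:
            raise ValueError(f"site position {pos} does not fit the genome")
        sequence = draw_site_sequence(pattern, rng)
        implanted = sequence if strand == "+" else reverse_complement(sequence)
        codes[pos : pos + patlen] = ["ACGT".index(b) for b in implanted]
        off = so if so is not None else 0
        if strand == "+":
            seed_start = pos + off
            boundary = seed_start
        else:
            seed_start = pos + patlen - off - k
            boundary = seed_start + k
        site = PlantedSite(
            genome_id=config.genome_id,
            position=pos,
            strand=strand,
            sequence=sequence,
            boundary=boundary,
            seed_start=seed_start,
            seed_end=seed_start + k,
        )
        if config.ensure_identifiable and so is not None:
            sequence = _enforce_identifiability(
                codes, site, pattern, config.seed_sequence, so, rng
            )
            site = PlantedSite(
                genome_id=site.genome_id,
                position=site.position,
                strand=site.strand,
                sequence=sequence,
                boundary=site.boundary,
                seed_start=site.seed_start,
                seed_end=site.seed_end,
            )
        truth.append(site)
    genome = GenomeSequence(config.genome_id, bytes(_BYTES[codes]).decode())
    return genome, truth


def simulate_packaging_coverage(
    genome: GenomeSequence,
    truth: list[PlantedSite],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    return_stats: bool = False,
):
    """Headful-packaging depth: jump at each boundary, staircase decay.

    Every event starts within ±``cut_jitter`` bp of the site boundary
    (oriented: a - series ends at ``boundary - jitter``, the exact mirror of
    a + series starting at ``boundary + jitter``) and increments depth by one
    over ``series_length * headful`` bases in the packaging direction,
    clipped at the genome ends. Per-base Poisson background is added before
    binning, so binned mass is conserved exactly in integer arithmetic.
    """
    rng = rng if rng is not None else config.rng()
    L = genome.length
    diff = np.zeros(L + 1, dtype=np.int64)
    total_event_bases = 0
    p = 1.0 / config.series_mean
    for site in truth:
        n = config.events_per_site
        if n == 0:
            continue
        if config.cut_jitter > 0:
            jitters = rng.integers(-config.cut_jitter, config.cut_jitter + 1, n)
        else:
            jitters = np.zeros(n, dtype=int)
        lengths = np.minimum(rng.geometric(p, n), config.series_max) * config.headful
        for j, span in zip(jitters, lengths):
            if site.strand == "+":
                a, b = site.boundary + int(j), site.boundary + int(j) + int(span)
            else:
                b = site.boundary - int(j)
                a = b - int(span)
            a, b = max(a, 0), min(b, L)
            if b > a:
                diff[a] += 1
                diff[b] -= 1
                total_event_bases += b - a
    signal = np.cumsum(diff[:-1])
    if config.background_rate > 0:
        background = rng.poisson(config.background_rate, L)
        signal = signal + background
        total_background = int(background.sum())
    else:
        total_background = 0
    n_bins = -(-L // config.binsize)
    starts = np.arange(0, L, config.binsize)
    sums = np.add.reduceat(signal, starts)
    widths = np.full(n_bins, config.binsize, dtype=int)
    widths[-1] = L - (n_bins - 1) * config.binsize
    track = CoverageTrack(genome.id, config.binsize, sums / widths, L)
    if return_stats:
        return track, {
            "total_event_bases": total_event_bases,
            "total_background": total_background,
        }
    return track


def expected_depth(config: SimulationConfig, distance: int) -> float:
    """Closed-form expected event depth ``distance`` bp downstream of a site.

    ``events_per_site * P(series_length * headful > distance)`` with the
    capped geometric series-length law; valid away from genome ends and
    ignoring the ±cut_jitter scatter (exact for cut_jitter = 0).
    """
    m = distance // config.headful + 1  # series length needed to cover
    if m > config.series_max:
        return 0.0
    p = 1.0 / config.series_mean
    return config.events_per_site * (1.0 - p) ** (m - 1)


@dataclass
class RecoveryReport:
    """End-to-end pipeline metrics against planted ground truth."""

    n_planted: int
    n_detected: int
    n_recovered: int
    recall: float
    n_spurious: int
    n_candidates_exact: int
    candidate_accuracy: float
    consensus_pattern: str | None
    consensus_contained: bool
    consensus_overlap_columns: int
    n_scan_matches: int
    scan_recall: float
    supported_fraction: float


def run_recovery_experiment(
    config: SimulationConfig,
    detection_params: DetectionParams | None = None,
    search_params: pac_search.SearchParams | None = None,
    flank: int = 20,
    max_variants: int = 3,
    position_tolerance_bins: int = 2,
) -> RecoveryReport:
    """Simulate, then run detect -> candidates -> consensus -> scan -> evidence.

    Recall counts planted sites with a detected site of the same strand
    within ``position_tolerance_bins`` bins of the true boundary; spurious
    sites are detections farther than ``min_separation`` from every planted
    boundary. A candidate is exact when it reproduces the planted seed-region
    coordinates and sequence. Consensus containment is checked column-wise
    against the generative pattern over the columns where the two overlap
    (anchored at the seed offset); a consensus run may extend into flanking
    sequence, which has no generative counterpart.
    """
    dp = detection_params or DetectionParams()
    sp = search_params or pac_search.SearchParams(seed=config.seed_sequence)
    rng = config.rng()
    genome, truth = simulate_genome(config, rng)
    track = simulate_packaging_coverage(genome, truth, config, rng)

    sites = detect_initiation_sites(track, dp)
    tol = position_tolerance_bins * config.binsize
    matched: dict[int, object] = {}
    for i, t in enumerate(truth):
        best = None
        for s in sites:
            if s.strand == t.strand and abs(s.position - t.boundary) <= tol:
                if best is None or abs(s.position - t.boundary) < abs(
                    best.position - t.boundary
                ):
                    best = s
        if best is not None:
            matched[i] = best
    n_spurious = sum(
        1
        for s in sites
        if all(abs(s.position - t.boundary) >= dp.min_separation for t in truth)
    )

    candidates = pac_search.find_candidates(genome, sites, sp)
    by_site = {id(c.site): c for c in candidates}
    n_exact = 0
    for i, t in enumerate(truth):
        s = matched.get(i)
        if s is None:
            continue
        c = by_site[id(s)]
        so = seed_offset(config.site_pattern, config.seed_sequence) or 0
        planted_seed_seq = t.sequence[so : so + len(config.seed_sequence)]
        if (
            c.start == t.seed_start
            and c.end == t.seed_end
            and c.seq == planted_seed_seq
        ):
            n_exact += 1

    consensus_pattern = None
    contained = False
    overlap = 0
    if len(candidates) >= 2:
        try:
            cons = build_consensus(
                align_candidates(candidates, genome, flank=flank),
                max_variants=max_variants,
            )
            consensus_pattern = str(cons)
            so = seed_offset(config.site_pattern, config.seed_sequence) or 0
            cs = cons.seed_span[0]
            contained = True
            for j, col in enumerate(cons.columns):
                gen_idx = j - cs + so
                if 0 <= gen_idx < config.site_pattern.n_columns:
                    overlap += 1
                    if not col <= config.site_pattern.columns[gen_idx]:
                        contained = False
        except PatternError:
            contained = False

    matches = genome_scan.scan_genome(genome, config.site_pattern)
    found = 0
    support = 0
    for t in truth:
        hit = next(
            (
                m
                for m in matches
                if m.start == t.position
                and m.end == t.position + config.site_pattern.n_columns
                and m.strand == t.strand
            ),
            None,
        )
        if hit is None:
            continue
        found += 1
        ev = evidence_mod.score_match_support(hit, track, dp)
        if ev.classification == "supported":
            support += 1

    n_truth = len(truth)
    return RecoveryReport(
        n_planted=n_truth,
        n_detected=len(sites),
        n_recovered=len(matched),
        recall=len(matched) / n_truth if n_truth else 1.0,
        n_spurious=n_spurious,
        n_candidates_exact=n_exact,
        candidate_accuracy=n_exact / n_truth if n_truth else 1.0,
        consensus_pattern=consensus_pattern,
        consensus_contained=contained,
        consensus_overlap_columns=overlap,
        n_scan_matches=len(matches),
        scan_recall=found / n_truth if n_truth else 1.0,
        supported_fraction=support / n_truth if n_truth else 1.0,
    )


def write_truth_bed(truth: list[PlantedSite], path: str | Path) -> None:
    """BED6 of planted sites; the name field carries sequence and boundary."""
    with open(path, "w") as fh:
        for i, t in enumerate(truth, 1):
            fh.write(
                f"{t.genome_id}\t{t.position}\t{t.position + len(t.sequence)}\t"
                f"site_{i};seq={t.sequence};boundary={t.boundary};"
                f"seed={t.seed_start}-{t.seed_end}\t0\t{t.strand}\n"
            )


def read_truth_bed(path: str | Path) -> list[PlantedSite]:
    truth = []
    with open(path) as fh:
        for line in fh:
            if not line.strip():
                continue
            chrom, start, _end, name, _score, strand = line.split("\t")[:6]
            fields = dict(
                part.split("=", 1) for part in name.split(";")[1:] if "=" in part
            )
            seed_start, seed_end = (int(x) for x in fields["seed"].split("-"))
            truth.append(
                PlantedSite(
                    genome_id=chrom,
                    position=int(start),
                    strand=strand.strip(),
                    sequence=fields["seq"],
                    boundary=int(fields["boundary"]),
                    seed_start=seed_start,
                    seed_end=seed_end,
                )
            )
    return truth
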