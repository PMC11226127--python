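# Methods

This document describes the model behind each pipeline stage, the default
parameters and how they were calibrated, and the known limitations of the
coverage generator.

## Biological model

Headful-packaging phages (P22-like) recognize a pac site on concatemeric
phage DNA, cut there, and package a processive series of fixed-length
"headfuls" in one direction until the series terminates. When the phage
occasionally initiates at a host sequence that resembles its pac site (a
*pseudo-pac* site), host DNA is packaged instead — the basis of generalized
transduction. In read coverage of packaged DNA mapped to the host genome,
such a site appears as:

* a sharp depth jump at the initiation boundary,
* a staircase decay in the packaging direction — each tread is one headful
  long and drops by the fraction of series that terminated there,
* an extent of several hundred kb (series of ~5 headfuls of ~43 kb).

The pipeline inverts this signature: detect boundaries from coverage, search
each boundary's neighborhood for the best pac-seed match, generalize the
matches into a degenerate consensus, scan for further matches genome-wide,
and classify every match by whether coverage actually supports initiation
there.

## Site detection (`site_detection`)

For a binned track (default 25 bp bins) and each bin boundary `b`, oriented
in a packaging direction, three statistics are computed:

* **jump ratio** `D / (U + 0.5)` where `D` and `U` are mean depths over
  `flank_bins` bins downstream and upstream of `b`. The 0.5 epsilon keeps
  the ratio finite on zero background; it is deliberately a constant, not
  data-dependent, so detection is scale-equivariant above the noise floor.
* **absolute jump** `D − U`.
* **decay fraction**: the fraction of adjacent bin pairs that are
  non-increasing over the next `decay_span_bins` bins (clamped at the track
  end).

Minus-strand sites are found by running the identical computation on the
reversed array, which makes detection exactly mirror-equivariant (this is a
tested invariant, not an approximation).

Boundaries passing all three gates are clustered by greedy non-maximum
suppression within `min_separation` bp, ranked by **absolute jump first**,
then ratio, then leftmost. The absolute jump peaks at the center of the
initiation ramp (the ±`cut_jitter` scatter of cut positions), whereas the
ratio keeps rising for a few bins past it (until the upstream flank clears
the ramp), so ranking by ratio would bias called positions downstream of the
true boundary by one to three bins.

### Default parameters and calibration

Defaults are calibrated on the simulator at its default conditions
(8 sites, 200 events each, 43 kb headfuls, geometric series mean 5, Poisson
background 1, 2 Mb genome), not on any particular sequencing run. On real
data the two jump thresholds are the ones to adjust first, roughly in
proportion to the event-to-background depth ratio.

| parameter            | default | rationale                                                                 |
|----------------------|---------|---------------------------------------------------------------------------|
| `flank_bins`         | 20      | 500 bp flanks: long enough to average out Poisson noise, short next to a 43 kb tread |
| `min_jump_ratio`     | 1.6     | overlapping series from neighboring sites raise the local baseline, so a true site's ratio is only ~2.0–2.3 (worst observed 1.99); headful stair steps stay below ~1.4 |
| `min_abs_jump`       | 5.0     | suppresses high-ratio boundaries on near-zero background at genome ends   |
| `decay_span_bins`    | 3440    | ~2 headfuls (86 kb): the window must span at least one stair drop          |
| `min_decay_fraction` | 0.45    | stair treads are flat, so adjacent pairs are non-increasing about half the time *whatever* the decay rate; the fraction concentrates near 0.5 at true sites (worst observed 0.51) and the gate only rejects windows dominated by fine-scale increase |
| `min_separation`     | 50,000  | about one headful; distinct sites closer than this are not separable from the jitter ramp anyway |

A note on the decay statistic: for stair-like decay the adjacent-pair
fraction is *not* a power-like measure of monotone decrease (a threshold of
0.6 would reject essentially every true site). It is kept because it is
robust and cheap, but it is a weak gate by design; the jump statistics carry
the detection.

## Candidate search (`pac_search`)

The machinery cuts within a ~120 bp region around the recognized sequence,
so each detected site is expanded into a 120 bp window centered on the
boundary, read 5'→3' on the packaging strand (reverse complemented for −
sites). The window is searched exhaustively for the substring minimizing
Hamming distance to the 12 bp seed `AAGATTTATCTG`; ties resolve to the
smallest window offset, and `N` matches nothing (not even `N`). Windows
running past a genome end are clamped with a warning; both search primitives
are verified against brute-force oracles in the test suite.

## Consensus construction (`consensus`)

Candidates are fixed-length ungapped best matches, so multiple alignment
reduces to stacking the oriented candidate sequences, extended by `flank`
(default 20) bp of genome context, with candidate starts in one column.
Flanks running past a genome end are padded with `N`.

Per column, the consensus base set is the smallest most-frequent-first set
of observed bases covering at least `min_rows_fraction` of the rows
(`N` ignored). At the default 1.0 this is exactly the set of bases observed
in the column; below 1.0 rare bases are dropped. A column is *conserved* iff
its set is non-empty and has at most `max_variants` (default 3) members.
The consensus is the maximal contiguous run of conserved columns containing
the anchored seed region, emitted in bracket notation (`AAG[AG]...`).

Because flanking columns can be conserved by chance in a small candidate
set, a consensus built from simulated sites may extend beyond the 17-column
generative pattern. *Containment* (used in the recovery experiment and
acceptance metrics) is therefore evaluated column-wise over the columns
where consensus and generative pattern overlap, anchored at the seed offset:
each overlapping consensus column must be a subset of the generative column.

The module also provides the pattern algebra used throughout: parsing and
canonical emission, cardinality (product of column set sizes, certified by
full enumeration in tests), column editing, diffing, seed-offset location,
and reverse complementation.

## Genome scanning (`genome_scan`)

Scanning is implemented directly over column base sets with numpy boolean
conjunctions, not through a regex engine. The minus strand is scanned by
matching the forward sequence against the reverse-complemented pattern, so
strand closure (`scan(revcomp(g))` equals the mirrored `scan(g)`) holds
exactly by construction. Overlapping matches and both orientations of a
palindromic hit are all reported. `N` matches no column.

## Evidence classification (`evidence`)

Each pattern match is scored with the same boundary statistics used for
detection, at the bin boundary nearest the match start (+ matches) or end
(− matches), oriented by the match strand. A match is `supported` iff it
passes the jump-ratio and decay gates. Matches the pattern proposes but
coverage does not support are reported as `unsupported` rather than
discarded: they may be masked by stronger neighboring initiation or blocked
by local DNA context, and on simulated data they are simply chance matches
of a degenerate pattern (about 2.4 expected per Mb per the cardinality).

The site table lists coverage-detected candidates first, then supported
scan-only hits, deduplicating scan hits that overlap a candidate locus on
the same strand. Table coordinates are 1-based inclusive; all BED artifacts
are standard 0-based half-open; all internal coordinates are 0-based
half-open.

## Coverage simulator (`simulate`)

The generator plants ground truth for every stage:

* **Genome**: i.i.d. uniform A/C/G/T background with one pattern draw
  (uniform per column) implanted per site; − sites implant the reverse
  complement. Default placement is an evenly spaced grid with ±10 kb jitter
  so the ≥2-headful separation invariant holds with realistic margins;
  `placement="random"` and explicit `site_positions` are available.
* **Boundary convention**: the coverage jump sits at the oriented start of
  the seed region — `seed_start` for + sites, `seed_end` for − sites.
* **Events**: each site receives `events_per_site` independent packaging
  events. An event starts uniformly within ±`cut_jitter` bp of the boundary
  (a − series *ends* at `boundary − jitter`, the exact mirror of a + series
  starting at `boundary + jitter`) and adds depth 1 over
  `series_length × headful` bases in the packaging direction, clipped at
  the genome ends (the genome is treated as linear).
* **Series length**: geometric with mean `series_mean`, capped at
  `series_max` (capped, not conditioned-truncated, so the tail law below the
  cap keeps the closed form `P(L ≥ m) = (1 − 1/mean)^(m−1)` used by
  `expected_depth` as an oracle).
* **Background**: per-base Poisson, added before binning, so binned mass is
  conserved exactly in integer arithmetic (a tested invariant).

### Identifiability

"The recovered candidate equals the planted sequence" is only meaningful if
the planted seed region is actually the best seed match nearby: a uniform
pattern draw sits ~4.2 mismatches from the seed, and some 12-mer in ~120 bp
of random background ties or beats that about 20% of the time per site. With
`ensure_identifiable=True` (default) the generator redraws background bases
(or the implant itself, when the competitor lies inside it) until the
planted seed-region 12-mer is the *strict* best Hamming match within reach
of any extraction window. This is a property of the ground truth's
well-definedness, not of the detector. Set it to `False` to measure
candidate accuracy under ambiguity.

### Generator limitations

* Depth is an event-count profile: no reads, read lengths, mapping errors,
  duplicates or mappability/GC bias are modeled — coverage noise is pure
  Poisson, which is optimistic about real dispersion.
* The headful length is exact and constant; real capsids vary by a few
  percent, which would blur stair edges at large tread numbers.
* The genome is linear; series running off the end are clipped rather than
  wrapped, so sites within ~`series_max × headful` of an end have truncated
  signatures.
* Cut jitter is uniform over ±`cut_jitter`; the real cut-position
  distribution is not modeled.
* The background sequence is i.i.d. uniform; real genomes have composition
  structure that changes the chance-match rate of degenerate patterns.
* Packaging events are independent across sites; competition for substrate
  between sites is not modeled beyond additive superposition of series.

## Determinism and numerics

All randomness flows from one `numpy` `default_rng` seed per run
(`SimulationConfig.seed`, `--seed` on the CLI and acceptance script); every
artifact is byte-reproducible for a given seed. Binned depth uses exact
integer sums divided by bin widths; full-bin bedGraph intervals re-enter bin
means directly so a written track reads back bit-identically. `repr()` of
Python floats (shortest round-trip form) is used in bedGraph output.
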