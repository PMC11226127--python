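"""Coverage-based support classification for pattern matches.

A pattern match is only a candidate packaging-initiation site; whether the
phage actually initiates there shows in the coverage profile. Each match is
scored with the same jump and decay statistics used for detection, evaluated
at the match coordinate in the orientation implied by the match strand, and
classified supported/unsupported with the detection thresholds. Matches the
pattern finds but coverage does not support may be masked by more prominent
packaging patterns at the same location or blocked by local DNA structure;
no structure prediction is attempted here.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import pandas as pd

from .coverage_io import CoverageTrack
from .genome_scan import PatternMatch
from .pac_search import PacCandidate
from .site_detection import DetectionParams, boundary_statistics


@dataclass(frozen=True)
class SiteEvidence:
    match: PatternMatch
    local_jump_ratio: float
    decay_fraction: float
    classification: str  # "supported" | "unsupported"


def score_match_support(
    match: PatternMatch,
    track: CoverageTrack,
    params: DetectionParams | None = None,
) -> SiteEvidence:
    """Score one match against the coverage track it should explain.

    For a + match packaging proceeds rightward from the match start; for a -
    match, leftward from the match end. The jump boundary is therefore the
    bin boundary nearest the match start (+) or end (-).
    """
    params = params or DetectionParams()
    if match.genome_id != track.genome_id:
        raise ValueError(
            f"match genome {match.genome_id!r} does not meet track genome "
            f"{track.genome_id!r}"
        )
    if match.start < 0 or match.end > track.genome_length:
        raise ValueError("match outside track extent")
    anchor = match.start if match.strand == "+" else match.end
    boundary = round(anchor / track.binsize)
    boundary = min(max(boundary, 1), track.n_bins - 1)
    ratio, _jump, decay = boundary_statistics(
        track.values, boundary, match.strand, params
    )
    supported = (
        ratio >= params.min_jump_ratio and decay >= params.min_decay_fraction
    )
    return SiteEvidence(
        match=match,
        local_jump_ratio=ratio,
        decay_fraction=decay,
        classification="supported" if supported else "unsupported",
    )


def summarize_sites(
    matches: list[PatternMatch],
    evidences: list[SiteEvidence],
    candidates: list[PacCandidate],
) -> pd.DataFrame:
    """Site table: coverage-detected sites first, then supported scan hits.

    Sites are numbered in order of detection provenance (coverage-detected
    candidates by position, then supported pattern matches by position);
    scan hits overlapping a candidate locus on the same strand are
    deduplicated. Coordinates are reported 1-based inclusive.
    """
    by_match = {id(e.match): e for e in evidences}
    rows = []
    seen = []
    for c in sorted(candidates, key=lambda c: (c.site.genome_id, c.start)):
        key = (c.site.genome_id, c.start, c.end, c.strand)
        if key in seen:
            continue
        seen.append(key)
        rows.append(
            dict(
                genome=c.site.genome_id,
                start=c.start + 1,
                end=c.end,
                strand=c.strand,
                sequence=c.seq,
                provenance="coverage",
            )
        )
    for m in sorted(matches, key=lambda m: (m.genome_id, m.start, m.strand != "+")):
        ev = by_match.get(id(m))
        if ev is None or ev.classification != "supported":
            continue
        dup = any(
            g == m.genome_id and s == m.strand and m.start < e_ and m.end > s_
            for g, s_, e_, s in seen
        )
        if dup or (m.genome_id, m.start, m.end, m.strand) in seen:
            continue
        seen.append((m.genome_id, m.start, m.end, m.strand))
        rows.append(
            dict(
                genome=m.genome_id,
                start=m.start + 1,
                end=m.end,
                strand=m.strand,
                sequence=m.matched_seq,
                provenance="scan",
            )
        )
    table = pd.DataFrame(
        rows, columns=["genome", "start", "end", "strand", "sequence", "provenance"]
    )
    table.insert(0, "site", range(1, len(table) + 1))
    return table


def write_site_table(table: pd.DataFrame, path: str | Path) -> None:
    """TSV site table; header comment documents the 1-based coordinates."""
    with open(path, "w") as fh:
        fh.write("# pseudo-pac site summary; start/end are 1-based inclusive\n")
        table.to_csv(fh, sep="\t", index=False)
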