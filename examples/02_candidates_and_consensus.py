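"""From detected sites to a degenerate consensus pattern.

The packaging machinery cuts within a ~120 bp region around its recognition
site, so each detected coverage jump is expanded into an oriented 120 bp
window and searched for the substring closest (in Hamming distance) to the
12 bp P22 pac seed. Stacking the oriented candidates with flanking context
and keeping the bases observed per column yields a bracket pattern such as
AAG[AG][TC]... that generalizes the individual sites.

Run with:  python examples/02_candidates_and_consensus.py
"""

from pseudopac import (
    P22_PAC_SEED,
    SimulationConfig,
    align_candidates,
    build_consensus,
    detect_initiation_sites,
    find_candidates,
    simulate_genome,
    simulate_packaging_coverage,
)

config = SimulationConfig(seed=1)
rng = config.rng()
genome, truth = simulate_genome(config, rng)
track = simulate_packaging_coverage(genome, truth, config, rng)
sites = detect_initiation_sites(track)

candidates = find_candidates(genome, sites)
print(f"pac seed: {P22_PAC_SEED}")
print(f"{len(candidates)} candidates (best seed match per site):")
for c in candidates:
    print(f"  {c.start:>10,}-{c.end:<10,} {c.strand}  {c.seq}  "
          f"({c.mismatches} mismatches)")

aligned = align_candidates(candidates, genome, flank=20)
print("\naligned rows (candidate region in columns "
      f"{aligned.anchor_col}-{aligned.anchor_col + aligned.seed_len}):")
for row in aligned.rows:
    print(f"  {row}")

consensus = build_consensus(aligned, max_variants=3)
print(f"\nconsensus ({consensus.n_columns} columns, "
      f"seed region {consensus.seed_span}):")
print(f"  {consensus}")

generative = config.site_pattern
print(f"\ngenerative pattern the sites were drawn from:")
print(f"  {generative}")
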