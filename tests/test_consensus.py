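import numpy as np
import pytest

from pseudopac import (
    DegenerateConsensus,
    GenomeSequence,
    P22_PAC_SEED,
    PSEUDO_PAC_PATTERN_INITIAL,
    PSEUDO_PAC_PATTERN_REFINED,
    align_candidates,
    build_consensus,
    diff_patterns,
    edit_column,
    emit_pattern,
    enumerate_sequences,
    parse_pattern,
    pattern_cardinality,
    reverse_complement,
    seed_offset,
)
from pseudopac.consensus import PatternError
from pseudopac.pac_search import PacCandidate
from conftest import make_site


def fake_candidate(genome, start, length, strand="+"):
    seq = genome.seq[start : start + length]
    if strand == "-":
        seq = reverse_complement(seq)
    return PacCandidate(
        site=make_site(start, strand, genome.id),
        seq=seq,
        start=start,
        end=start + length,
        strand=strand,
        mismatches=0,
    )


def random_pattern(rng, n_cols):
    cols = []
    for _ in range(n_cols):
        size = int(rng.integers(1, 5))
        cols.append(frozenset(rng.choice(list("ACGT"), size=size, replace=False)))
    return DegenerateConsensus(tuple(cols))


# ------------------------------------------------------------ parse / emit


def test_initial_pattern_has_17_columns_and_cardinality_10368():
    c = parse_pattern(PSEUDO_PAC_PATTERN_INITIAL)
    assert c.n_columns == 17
    assert pattern_cardinality(c) == 10368
    seqs = set(enumerate_sequences(c))
    assert len(seqs) == 10368
    assert all(c.matches(s) for s in seqs)


def test_refined_pattern_cardinality_20736():
    c = parse_pattern(PSEUDO_PAC_PATTERN_REFINED)
    assert c.n_columns == 17
    assert pattern_cardinality(c) == 20736
    assert sum(1 for _ in enumerate_sequences(c)) == 20736


def test_refined_differs_from_initial_only_at_column_3():
    initial = parse_pattern(PSEUDO_PAC_PATTERN_INITIAL)
    refined = parse_pattern(PSEUDO_PAC_PATTERN_REFINED)
    assert diff_patterns(initial, refined) == [3]
    assert edit_column(initial, 3, "GC").columns == refined.columns


def test_seed_is_compatible_with_both_patterns_at_offset_0():
    assert seed_offset(parse_pattern(PSEUDO_PAC_PATTERN_INITIAL)) == 0
    assert seed_offset(parse_pattern(PSEUDO_PAC_PATTERN_REFINED)) == 0
    assert seed_offset(parse_pattern("CCCC"), "AA") is None


def test_parse_tolerates_whitespace_inside_pattern():
    spaced = "AA[GC][AG][TC][AT][AT][ATC][TC][TC]T[GT][ACG][ACG] [ACG]TC"
    assert parse_pattern(spaced).columns == parse_pattern(
        PSEUDO_PAC_PATTERN_REFINED
    ).columns


def test_parse_errors():
    for bad in ("", "AAG[", "AAG[]T", "AAX", "A[GU]"):
        with pytest.raises(PatternError):
            parse_pattern(bad)


def test_emit_parse_roundtrip_on_random_patterns():
    rng = np.random.default_rng(13)
    for _ in range(200):
        c = random_pattern(rng, int(rng.integers(1, 20)))
        assert parse_pattern(emit_pattern(c)).columns == c.columns


def test_emit_is_canonical():
    assert emit_pattern(parse_pattern("[GA][A][TGCA]")) == "[AG]A[ACGT]"


def test_matches_rejects_n_and_wrong_length():
    c = parse_pattern("A[AC]G")
    assert c.matches("ACG")
    assert not c.matches("ANG")
    assert not c.matches("AC")


def test_reverse_complement_involution_and_seed_span():
    c = parse_pattern(PSEUDO_PAC_PATTERN_REFINED, seed_span=(0, 12))
    rc = c.reverse_complement()
    assert rc.seed_span == (5, 17)
    assert rc.reverse_complement() == c
    # complementation is column-wise: last column of rc complements column 0
    assert rc.columns[-1] == frozenset("T")


def test_diff_patterns_requires_equal_length():
    with pytest.raises(PatternError):
        diff_patterns(parse_pattern("AA"), parse_pattern("AAA"))


def test_edit_column_bounds():
    c = parse_pattern("ACGT")
    with pytest.raises(PatternError):
        edit_column(c, 0, "A")
    with pytest.raises(PatternError):
        edit_column(c, 5, "A")


# ------------------------------------------------------------ consensus


def test_two_row_consensus_from_spec_example():
    # rows AAGA and AAGG, no flank: consensus AAG[AG]
    g1 = GenomeSequence("g1", "AAGA")
    g2 = GenomeSequence("g2", "AAGG")
    cands = [fake_candidate(g1, 0, 4), fake_candidate(g2, 0, 4)]
    aligned = align_candidates(cands, {"g1": g1, "g2": g2}, flank=0)
    cons = build_consensus(aligned)
    assert str(cons) == "AAG[AG]"
    assert cons.seed_span == (0, 4)


def test_consensus_is_sound_for_every_input_row():
    rng = np.random.default_rng(21)
    genome = GenomeSequence(
        "g", "".join(rng.choice(list("ACGT"), size=3000))
    )
    cands = [
        fake_candidate(genome, int(p), 12, strand)
        for p, strand in [(100, "+"), (700, "-"), (1500, "+"), (2300, "-")]
    ]
    aligned = align_candidates(cands, genome, flank=20)
    cons = build_consensus(aligned, max_variants=4)
    s, e = (
        aligned.anchor_col - cons.seed_span[0],
        aligned.anchor_col - cons.seed_span[0] + cons.n_columns,
    )
    for row in aligned.rows:
        assert cons.matches(row[s:e])


def test_column_with_four_variants_breaks_the_run():
    rows = ["ACCA", "GCCA", "CCCA", "TCCA"]
    genomes = {f"g{i}": GenomeSequence(f"g{i}", r) for i, r in enumerate(rows)}
    cands = [fake_candidate(g, 1, 3) for g in genomes.values()]
    aligned = align_candidates(cands, genomes, flank=1)
    cons = build_consensus(aligned, max_variants=3)
    # the first aligned column sees A/G/C/T and is dropped; CCA remains
    assert str(cons) == "CCA"
    assert cons.seed_span == (0, 3)


def test_min_rows_fraction_drops_rare_bases():
    rows = ["AC", "AC", "AC", "GC"]
    genomes = {f"g{i}": GenomeSequence(f"g{i}", r) for i, r in enumerate(rows)}
    cands = [fake_candidate(g, 0, 2) for g in genomes.values()]
    aligned = align_candidates(cands, genomes, flank=0)
    assert str(build_consensus(aligned)) == "[AG]C"
    assert str(build_consensus(aligned, min_rows_fraction=0.75)) == "AC"


def test_consensus_is_invariant_to_candidate_order():
    rng = np.random.default_rng(8)
    genome = GenomeSequence("g", "".join(rng.choice(list("ACGT"), size=2000)))
    cands = [
        fake_candidate(genome, p, 12, s)
        for p, s in [(200, "+"), (600, "-"), (1000, "+"), (1500, "-")]
    ]
    ref = str(build_consensus(align_candidates(cands, genome)))
    for _ in range(5):
        rng.shuffle(cands)
        assert str(build_consensus(align_candidates(cands, genome))) == ref


def test_flanks_past_genome_end_are_padded_with_n():
    g1 = GenomeSequence("g1", "AAGATT")
    g2 = GenomeSequence("g2", "CAAGATTC")
    cands = [fake_candidate(g1, 0, 6), fake_candidate(g2, 1, 6)]
    aligned = align_candidates(cands, {"g1": g1, "g2": g2}, flank=2)
    assert aligned.rows[0] == "NNAAGATTNN"
    assert aligned.rows[1] == "NCAAGATTCN"
    cons = build_consensus(aligned)
    # all-N columns are unconserved; single-genome flank columns survive
    assert str(cons) == "CAAGATTC"


def test_consensus_requires_two_candidates():
    genome = GenomeSequence("g", "ACGTACGTACGT")
    with pytest.raises(PatternError):
        align_candidates([fake_candidate(genome, 0, 4)], genome)


def test_random_draws_all_match_their_pattern():
    from pseudopac import draw_site_sequence

    rng = np.random.default_rng(4)
    for _ in range(50):
        c = random_pattern(rng, int(rng.integers(1, 12)))
        for _ in range(5):
            assert c.matches(draw_site_sequence(c, rng))
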