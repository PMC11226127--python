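import numpy as np
import pytest

from pseudopac import (
    GenomeSequence,
    P22_PAC_SEED,
    PSEUDO_PAC_PATTERN_REFINED,
    SimulationConfig,
    best_match,
    draw_site_sequence,
    expected_depth,
    extract_window,
    parse_pattern,
    reverse_complement,
    run_recovery_experiment,
    scan_genome,
    simulate_genome,
    simulate_packaging_coverage,
)
from pseudopac.simulate import PlantedSite, read_truth_bed, write_truth_bed
from conftest import make_site


def small_config(**overrides):
    kwargs = dict(genome_length=500_000, n_sites=2, seed=5)
    kwargs.update(overrides)
    return SimulationConfig(**kwargs)


# ------------------------------------------------------------ genome


def test_config_validation():
    for bad in (
        dict(headful=0),
        dict(series_mean=0.5),
        dict(genome_length=0),
        dict(cut_jitter=-1),
        dict(background_rate=-1.0),
    ):
        with pytest.raises(ValueError):
            SimulationConfig(**bad)


def test_draw_site_sequence_is_uniform_per_column():
    pattern = parse_pattern(PSEUDO_PAC_PATTERN_REFINED)
    rng = np.random.default_rng(2)
    n = 6000
    draws = [draw_site_sequence(pattern, rng) for _ in range(n)]
    assert all(pattern.matches(d) for d in draws)
    for j, col in enumerate(pattern.columns):
        if len(col) == 1:
            continue
        p = 1 / len(col)
        se = np.sqrt(n * p * (1 - p))
        for base in col:
            count = sum(d[j] == base for d in draws)
            assert abs(count - n * p) <= 3 * se


def test_planted_sequences_are_implanted_at_truth_coordinates():
    config = small_config(strand_assignment=["+", "-"])
    genome, truth = simulate_genome(config)
    assert [t.strand for t in truth] == ["+", "-"]
    for t in truth:
        piece = genome.seq[t.position : t.position + 17]
        oriented = piece if t.strand == "+" else reverse_complement(piece)
        assert oriented == t.sequence
        assert config.site_pattern.matches(t.sequence)
        # boundary sits at the oriented start of the seed region
        if t.strand == "+":
            assert t.boundary == t.seed_start == t.position
        else:
            assert t.boundary == t.seed_end == t.position + 17


def test_planted_site_is_the_best_seed_match_in_its_window():
    config = small_config(n_sites=4, genome_length=800_000, seed=9)
    genome, truth = simulate_genome(config)
    for t in truth:
        site = make_site(t.boundary, t.strand)
        window = extract_window(genome, site, 120)
        off, _seq, _d = best_match(window.seq, P22_PAC_SEED)
        start, end = window.to_forward(off, 12)
        assert (start, end) == (t.seed_start, t.seed_end)


def test_scan_finds_every_planted_site():
    config = small_config(seed=6)
    genome, truth = simulate_genome(config)
    hits = {
        (m.start, m.strand) for m in scan_genome(genome, config.site_pattern)
    }
    assert {(t.position, t.strand) for t in truth} <= hits


def test_zero_sites_gives_pure_background():
    config = SimulationConfig(genome_length=100_000, n_sites=0, seed=1)
    rng = config.rng()
    genome, truth = simulate_genome(config, rng)
    assert truth == []
    track = simulate_packaging_coverage(genome, truth, config, rng)
    mean = track.values.mean()
    se = np.sqrt(config.background_rate / config.genome_length)
    assert abs(mean - config.background_rate) <= 3 * se


def test_placement_respects_separation_and_errors_when_impossible():
    config = small_config(n_sites=5, genome_length=2_000_000, placement="random",
                          seed=3)
    _, truth = simulate_genome(config)
    positions = sorted(t.position for t in truth)
    assert min(np.diff(positions)) >= 2 * config.headful
    with pytest.raises(ValueError, match="placed"):
        simulate_genome(SimulationConfig(genome_length=100_000, n_sites=4))
    with pytest.raises(ValueError, match="site_positions"):
        simulate_genome(small_config(site_positions=[1000]))


# ------------------------------------------------------------ coverage


def test_single_series_coverage_is_exact():
    # series_mean 1 makes every event exactly one headful, jitter 0 and
    # background 0 make the profile deterministic
    config = SimulationConfig(
        genome_length=100_000,
        n_sites=1,
        site_positions=[40_000],
        strand_assignment="+",
        series_mean=1.0,
        cut_jitter=0,
        background_rate=0.0,
        events_per_site=10,
        headful=20_000,
        seed=0,
    )
    rng = config.rng()
    genome, truth = simulate_genome(config, rng)
    track = simulate_packaging_coverage(genome, truth, config, rng)
    boundary = truth[0].boundary
    expected = np.zeros(100_000)
    expected[boundary : boundary + 20_000] = 10.0
    binned = expected.reshape(-1, 25).mean(axis=1)
    assert np.array_equal(track.values, binned)


def test_total_coverage_mass_is_conserved():
    config = small_config(seed=8)
    rng = config.rng()
    genome, truth = simulate_genome(config, rng)
    track, stats = simulate_packaging_coverage(
        genome, truth, config, rng, return_stats=True
    )
    total = stats["total_event_bases"] + stats["total_background"]
    assert round(track.total_depth()) == total


def test_minus_strand_coverage_is_exact_mirror_of_plus():
    L = 200_000
    genome = GenomeSequence("sim", "A" * L)
    config = SimulationConfig(
        genome_length=L, n_sites=1, background_rate=0.0, seed=4
    )
    plus = [PlantedSite("sim", 80_000, "+", "A" * 17, 80_000, 80_000, 80_012)]
    minus = [
        PlantedSite(
            "sim", L - 80_017, "-", "A" * 17, L - 80_000, L - 80_012, L - 80_000
        )
    ]
    t_plus = simulate_packaging_coverage(genome, plus, config, config.rng())
    t_minus = simulate_packaging_coverage(genome, minus, config, config.rng())
    assert np.array_equal(t_minus.values, t_plus.values[::-1])


def test_coverage_tracks_expected_depth_staircase():
    config = SimulationConfig(
        genome_length=700_000,
        n_sites=1,
        site_positions=[100_000],
        strand_assignment="+",
        cut_jitter=0,
        background_rate=0.0,
        events_per_site=400,
        seed=12,
    )
    rng = config.rng()
    genome, truth = simulate_genome(config, rng)
    track = simulate_packaging_coverage(genome, truth, config, rng)
    boundary = truth[0].boundary
    p = 1.0 / config.series_mean
    for treads in range(4):
        distance = treads * config.headful + 1000
        depth = track.values[(boundary + distance) // config.binsize]
        mu = expected_depth(config, distance)
        q = (1 - p) ** treads
        se = np.sqrt(config.events_per_site * q * (1 - q)) or 1.0
        assert abs(depth - mu) <= 3 * se


def test_expected_depth_closed_form():
    config = SimulationConfig()
    assert expected_depth(config, 0) == config.events_per_site
    assert expected_depth(config, config.headful) == pytest.approx(
        config.events_per_site * 0.8
    )
    assert expected_depth(config, config.headful * config.series_max) == 0.0


# ------------------------------------------------------------ end to end


def test_recovery_experiment_on_small_config():
    report = run_recovery_experiment(small_config(seed=17))
    assert report.n_planted == 2
    assert report.recall == 1.0
    assert report.n_spurious == 0
    assert report.candidate_accuracy == 1.0
    assert report.scan_recall == 1.0
    assert report.supported_fraction == 1.0
    assert report.consensus_pattern is not None


def test_truth_bed_roundtrip(tmp_path):
    _, truth = simulate_genome(small_config())
    path = tmp_path / "truth.bed"
    write_truth_bed(truth, path)
    assert read_truth_bed(path) == truth
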