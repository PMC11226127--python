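"""Shared helpers for the test suite."""

import numpy as np
import pytest

from pseudopac import GenomeSequence, InitiationSite


@pytest.fixture
def rng():
    return np.random.default_rng(0)


def random_genome(rng, length, genome_id="g", with_n=False):
    alphabet = "ACGTN" if with_n else "ACGT"
    probs = [0.23, 0.23, 0.23, 0.23, 0.08] if with_n else None
    seq = "".join(rng.choice(list(alphabet), size=length, p=probs))
    return GenomeSequence(genome_id, seq)


def make_site(position, strand="+", genome_id="g"):
    return InitiationSite(
        genome_id=genome_id,
        position=position,
        strand=strand,
        jump_ratio=10.0,
        decay_fraction=1.0,
        abs_jump=50.0,
    )
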