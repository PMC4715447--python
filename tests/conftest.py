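"""Shared fixtures: one desk-scale simulated instance reused across modules."""

from __future__ import annotations

import numpy as np
import pytest

from mitoforge.seqio import GenomeSequence
from mitoforge.simulate import (
    SimConfig,
    random_read_pool,
    simulate_mitogenome,
    simulate_reads,
    truth_references,
)

DESK_COVERAGE = 120.0
SEED = 3


@pytest.fixture(scope="session")
def sim_cfg() -> SimConfig:
    return SimConfig(seed=SEED, coverage=DESK_COVERAGE)


@pytest.fixture(scope="session")
def truth(sim_cfg):
    """(genome, annotation) of the simulated truth circle."""
    return simulate_mitogenome(sim_cfg)


@pytest.fixture(scope="session")
def truth_genome(truth) -> GenomeSequence:
    return truth[0]


@pytest.fixture(scope="session")
def truth_ann(truth):
    return truth[1]


@pytest.fixture(scope="session")
def read_libs(truth_genome, sim_cfg):
    return simulate_reads(truth_genome, sim_cfg)


@pytest.fixture(scope="session")
def read_pairs(read_libs):
    return read_libs["insert250"] + read_libs["insert500"]


@pytest.fixture(scope="session")
def all_reads(read_pairs):
    return [r for a, b in read_pairs for r in (a, b)]


@pytest.fixture(scope="session")
def clean_read_pairs(truth_genome, sim_cfg):
    """Error-free reads from the same truth genome."""
    cfg = SimConfig(seed=SEED, coverage=DESK_COVERAGE, sub_error_rate=0.0)
    libs = simulate_reads(truth_genome, cfg)
    return libs["insert250"] + libs["insert500"]


@pytest.fixture(scope="session")
def divergent_reference(truth_genome):
    """A 5%-divergent copy of the truth, standing in for a related species."""
    rng = np.random.default_rng(42)
    bases = list(truth_genome.bases)
    idx = rng.choice(len(bases), size=int(0.05 * len(bases)), replace=False)
    for i in idx:
        alt = [b for b in "ACGT" if b != bases[i]]
        bases[i] = alt[int(rng.integers(0, 3))]
    return GenomeSequence(id="related_species", bases="".join(bases))


@pytest.fixture(scope="session")
def background_pairs(read_pairs):
    """Random-sequence pairs of equal mass to the mitochondrial pool."""
    pool = random_read_pool(2 * len(read_pairs), seed=5)
    return [(pool[i], pool[i + 1]) for i in range(0, len(pool) - 1, 2)]


@pytest.fixture(scope="session")
def truth_refs(truth_genome, truth_ann):
    """(protein references, RNA references) from the truth annotation."""
    return truth_references(truth_genome, truth_ann)
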