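import pytest

from coldmir.fold import get_backend
from coldmir.syn_data import (
    LengthNoise,
    ReadSimulationParams,
    SyntheticGenomeSpec,
    build_genome,
)

# Small study-shaped fixture: 3 chromosomes, planted known families, novel
# hairpins and ncRNA contaminants.  Session-scoped because hairpin planting
# folds RNA on every retry.
FIXTURE_SPEC = SyntheticGenomeSpec(
    genome_length=60_000,
    n_chromosomes=3,
    n_known_loci=6,
    n_novel_loci=4,
    n_ncrna_loci=6,
    gc_fraction=0.35,
    seed=11,
)


@pytest.fixture(scope="session")
def backend():
    return get_backend("vienna")


@pytest.fixture(scope="session")
def genome_truth(backend):
    return build_genome(FIXTURE_SPEC, backend=backend)


@pytest.fixture(scope="session")
def genome(genome_truth):
    return genome_truth[0]


@pytest.fixture(scope="session")
def truth(genome_truth):
    return genome_truth[1]


def noiseless_params(seed: int = 1, total: int | None = 40_000) -> ReadSimulationParams:
    """Error-free, offset-free simulation parameters for exact-recovery tests."""
    return ReadSimulationParams(
        total_reads_per_library=total,
        length_noise=LengthNoise(p=0.0),
        sequencing_error_rate=0.0,
        seed=seed,
    )
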