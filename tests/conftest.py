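import numpy as np
import pytest

from spaceracq import (
    CRISPRArraySpec,
    SimulationConfig,
    default_array_spec,
    generate_host_genomes,
    generate_phage_genome,
)


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """A fast study configuration shared by integration-style tests."""
    return SimulationConfig(seed=11, n_reads=2000, error_rate=0.0)


@pytest.fixture(scope="session")
def phage(small_config):
    return generate_phage_genome(small_config)


@pytest.fixture(scope="session")
def hosts(small_config):
    return generate_host_genomes(small_config)


@pytest.fixture(scope="session")
def array(small_config) -> CRISPRArraySpec:
    return default_array_spec(small_config)


@pytest.fixture()
def rng():
    return np.random.default_rng(42)


def make_array(repeat_len: int = 36, seed: int = 5) -> CRISPRArraySpec:
    """A tiny deterministic array spec for unit tests."""
    r = np.random.default_rng(seed)
    bases = np.frombuffer(b"ACGT", dtype=np.uint8)

    def dna(n):
        return r.choice(bases, size=n).tobytes().decode()

    leader = dna(60)
    spacers = [dna(38) for _ in range(3)]
    return CRISPRArraySpec(
        array_id="unit-test-array",
        repeat=dna(repeat_len),
        spacers=spacers,
        leader=leader,
        amplicon_primers=(leader[-40:][:20], "TTTTACGTACGTACGTAAAA"),
    )
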