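import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from tn5prefer.core_io import GenomeSequence
from tn5prefer import synthetic

settings.register_profile(
    "ci", derandomize=True, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def toy_genome() -> GenomeSequence:
    """20-kb uniform random genome, fixed seed."""
    cfg = synthetic.SimulationConfig(genome_length=20_000, seed=12345)
    return synthetic.simulate_genome(cfg)


@pytest.fixture(scope="session")
def toy_fasta(tmp_path_factory, toy_genome):
    from tn5prefer.core_io import write_fasta

    path = tmp_path_factory.mktemp("genome") / "toy.fa"
    write_fasta(toy_genome, path)
    return path


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(2024)


def random_window(rng: np.random.Generator, length: int = 51) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, length))
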