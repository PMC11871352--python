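import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from mitocompare.synthetic_data import default_genome_spec, generate_mitogenome

settings.register_profile(
    "suite",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
    deadline=None,
)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def synthetic_genome(tmp_path_factory):
    """One deterministic synthetic mitogenome, its GenBank file and the
    generator's ground truth, shared across the suite."""
    path = tmp_path_factory.mktemp("genomes") / "syn7.gb"
    record, truth = generate_mitogenome(default_genome_spec(seed=7), path)
    return record, truth, path


@pytest.fixture(scope="session")
def second_genome(tmp_path_factory):
    path = tmp_path_factory.mktemp("genomes") / "syn11.gb"
    record, truth = generate_mitogenome(default_genome_spec(seed=11), path)
    return record, truth, path


@pytest.fixture()
def rng():
    return np.random.default_rng(20260930)


def random_dna(rng, n: int) -> str:
    return "".join(rng.choice(np.array(list("ACGT")), size=n))
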