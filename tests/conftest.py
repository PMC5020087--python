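import numpy as np
import pytest

from ssrforge import mining, synthetic


@pytest.fixture(scope="session")
def default_config():
    return mining.MiningConfig()


@pytest.fixture(scope="session")
def planted_genome():
    """A 60 kb genome with 12 planted tracts and its truth table."""
    rng = np.random.default_rng(42)
    plants = synthetic.random_plants(12, rng, units=(2, 3, 4), copies_range=(5, 15))
    spec = synthetic.PlantSpec(seq_lengths=[60_000], plants=plants, seed=42)
    records, truth = synthetic.generate_genome(
        spec, verify_config=mining.MiningConfig()
    )
    return records, truth


@pytest.fixture(scope="session")
def mined_loci(planted_genome, default_config):
    records, _ = planted_genome
    loci, summary = mining.mine_genome(records, default_config)
    return loci, summary


@pytest.fixture(scope="session")
def two_seq_genome():
    """Two 30 kb sequences with tracts on both, for per-sequence statistics."""
    rng = np.random.default_rng(9)
    plants = synthetic.random_plants(
        10, rng, n_seqs=2, units=(2, 3), copies_range=(5, 10)
    )
    spec = synthetic.PlantSpec(seq_lengths=[30_000, 30_000], plants=plants, seed=9)
    return synthetic.generate_genome(spec, verify_config=mining.MiningConfig())
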