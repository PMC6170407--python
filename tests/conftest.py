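import numpy as np
import pytest

import bidirscan as b


@pytest.fixture(scope="session")
def demo_config() -> b.SimulationConfig:
    """The 300-gene demo study with 5x crosslink enrichment at loading sites."""
    return b.SimulationConfig(seed=42, crosslink_enrichment=5.0)


@pytest.fixture(scope="session")
def demo_result(demo_config) -> b.PipelineResult:
    """One full pipeline run shared by the slower end-to-end tests."""
    return b.run_full(demo_config)


@pytest.fixture(scope="session")
def small_truth():
    """A small simulated locus set for track/metaprofile tests."""
    cfg = b.SimulationConfig(
        seed=1, n_chroms=1, chrom_length=1_500_000, n_genes=80, n_reads=80_000
    )
    truth = b.simulate_genome(cfg)
    return cfg, truth


def random_dna(rng: np.random.Generator, n: int) -> str:
    return "".join(rng.choice(list("ACGT"), n))
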