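import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")

from poolrare import (
    DepthModel,
    NoiseModel,
    generate_cohort,
    generate_panel,
    build_pools,
)


@pytest.fixture(scope="session")
def small_panel():
    """24 genes x 6 amplicons — enough distinct genes for 21 spiked variants."""
    return generate_panel(n_genes=24, amplicons_per_gene=6, seed=11)


@pytest.fixture(scope="session")
def spiked_cohort(small_panel):
    """112 samples; 21 distinct het control variants carried by 16 samples."""
    genes = small_panel.genes
    spike = [(genes[i % len(genes)], "het", 1) for i in range(21)]
    candidates = [f"S{i + 1:04d}" for i in range(16)]
    return generate_cohort(
        small_panel, 112, spike, seed=12, carrier_candidates=candidates
    )


@pytest.fixture(scope="session")
def seven_pools(spiked_cohort):
    return build_pools(spiked_cohort, pool_size=16, controls_per_pool=2, seed=13)


@pytest.fixture(scope="session")
def default_depth():
    return DepthModel()


@pytest.fixture(scope="session")
def default_noise():
    return NoiseModel()
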