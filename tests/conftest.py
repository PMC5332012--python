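import numpy as np
import pytest
from hypothesis import HealthCheck, settings

settings.register_profile(
    "suite",
    max_examples=25,
    deadline=None,
    derandomize=True,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("suite")


@pytest.fixture
def rng():
    return np.random.default_rng(20170301)


@pytest.fixture(scope="session")
def mini_screen(tmp_path_factory):
    """A small error-free simulated screen shared by integration tests."""
    from bartrap.simulate import SimConfig, simulate_screen

    cfg = SimConfig(
        seed=11,
        n_chroms=2,
        chrom_length=100_000,
        n_genes=20,
        gene_length=4_000,
        n_pools=1,
        n_mutants_per_pool=200,
        barcode_pool_size=None,
        multi_copy_fraction=0.05,
        reads_per_sample=60_000,
        invpcr_reads_per_site=60,
        error_rate=0.0,
    )
    out = tmp_path_factory.mktemp("mini_screen")
    sim = simulate_screen(cfg, out)
    sim["config"] = cfg
    return sim
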