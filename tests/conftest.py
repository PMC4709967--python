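import numpy as np
import pytest

from esccpipe.simulate import SimConfig, simulate_cohort


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


@pytest.fixture(scope="session")
def small_sim():
    """A small simulated cohort shared across read-only tests."""
    cfg = SimConfig(
        seed=7,
        n_stage1=12,
        n_stage3=12,
        genome=(("chr1", 100_000), ("chr2", 100_000)),
        n_genes=30,
        n_sites=24,
        segment_bp=10_000,
    )
    return simulate_cohort(cfg)
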