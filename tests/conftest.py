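import numpy as np
import pytest

from quadte.synth import SyntheticConfig, generate, worked_example_fixture


@pytest.fixture(scope="session")
def small_dataset():
    """30-gene synthetic dataset with the default planted scenario, scaled down."""
    cfg = SyntheticConfig(seed=11, n_genes=30, n_utr5_rg4_bound=6,
                          n_cds_bound=2, n_utr3_are_bound=2)
    return generate(cfg)


@pytest.fixture(scope="session")
def mini_fixture():
    """Deterministic 10-gene worked-example dataset."""
    return worked_example_fixture()


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
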