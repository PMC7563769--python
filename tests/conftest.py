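import numpy as np
import pandas as pd
import pytest

from pcsig.synthetic_data import SimConfig, generate_experiment


@pytest.fixture(scope="session")
def small_bundle():
    """Fast synthetic experiment for unit tests (400 genes, strong effects)."""
    cfg = SimConfig(
        n_genes=400,
        n_de_genes=40,
        n_pathways=11,
        pathway_size=20,
        seed=7,
    )
    return generate_experiment(cfg)


@pytest.fixture(scope="session")
def default_bundle():
    """The study-condition experiment used by the end-to-end checks."""
    return generate_experiment(SimConfig(seed=1))


@pytest.fixture()
def tiny_matrix():
    """2 genes x 3 samples, hand-enterable values."""
    return pd.DataFrame(
        [[1.0, 2.0, 3.0], [4.0, 5.0, 6.0]],
        index=["g1", "g2"],
        columns=["s1", "s2", "s3"],
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(2024)
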