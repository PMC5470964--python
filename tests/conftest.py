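import numpy as np
import pandas as pd
import pytest

from rtsig.io import ExpressionMatrix
from rtsig.simulate import SimulationConfig, generate_expression


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 2 samples."""
    return ExpressionMatrix(pd.DataFrame(
        [[5.0, 6.0], [7.5, 7.0], [3.2, 4.1]],
        index=["G1", "G2", "G3"], columns=["S1", "S2"]))


@pytest.fixture(scope="session")
def small_config() -> SimulationConfig:
    """Reduced gene count for fast unit tests; cohort sizes are standard."""
    return SimulationConfig(n_genes=400, n_signature=60,
                            subtype_block_size=20, other_block_size=30,
                            seed=7)


@pytest.fixture(scope="session")
def small_cohort(small_config):
    return generate_expression(small_config)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(1234)
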