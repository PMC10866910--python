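import numpy as np
import pandas as pd
import pytest

from tsescore.signature_io import ExpressionMatrix, SignatureSet
from tsescore.synthetic_cohort import SimulationConfig, generate_cohort


@pytest.fixture
def hand_matrix() -> ExpressionMatrix:
    """4-gene x 3-sample matrix used by the hand-computed scoring oracle.

    Per-gene medians: g1 -> 2, g2 -> 0, g3 -> 1, g4 -> 2.
    Centered values:
        g1: -1  0  2
        g2:  0  0  3
        g3:  4  0  0
        g4:  0  6  0
    """
    values = np.array(
        [
            [1.0, 2.0, 4.0],
            [0.0, 0.0, 3.0],
            [5.0, 1.0, 1.0],
            [2.0, 8.0, 2.0],
        ]
    )
    return ExpressionMatrix(values, ["g1", "g2", "g3", "g4"], ["s1", "s2", "s3"])


@pytest.fixture
def hand_signatures() -> SignatureSet:
    return SignatureSet(
        signatures={"SigT": ["g1", "g2"], "SigS": ["g3", "g4"]},
        group={"SigT": "T-cell", "SigS": "stromal"},
        global_T_members=["SigT"],
        global_S_members=["SigS"],
    )


@pytest.fixture(scope="session")
def default_cohort():
    return generate_cohort(SimulationConfig(seed=11))


@pytest.fixture
def small_config() -> SimulationConfig:
    """Fast cohort for tests that iterate over many seeds."""
    return SimulationConfig(n_samples=120, n_genes=400, seed=0)
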