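import numpy as np
import pytest

from copong.data import ExpressionMatrix, HOGMap, OrthologyMap, ProbeGeneMap
from copong.simulate import SimConfig, simulate_pair


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_expr():
    return ExpressionMatrix(
        species="human",
        feature_ids=["g1", "g2", "g3"],
        sample_ids=["s1", "s2", "s3", "s4"],
        values=np.array(
            [[2.0, 4.0, 1.0, 3.0], [0.0, 1.0, 2.0, 3.0], [5.0, 5.0, 0.0, 0.0]]
        ),
    )


@pytest.fixture
def planted_dataset():
    """One deterministic synthetic paired-species data set with planted
    co-modules, shared by recovery-style tests."""
    cfg = SimConfig(seed=7)
    return cfg, simulate_pair(cfg)
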