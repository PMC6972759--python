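import numpy as np
import pytest

from craet.model import (
    CONCEPT,
    FEATURE,
    ORDER_DEPENDENT,
    ORDER_INDEPENDENT,
    NetworkState,
    ThresholdSpec,
)
from craet.pipeline import RunConfig, run_protocol


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def empty_net():
    """A network with one absolute-threshold Euclidean feature area."""
    net = NetworkState(seed=0)
    net.ensure_area(FEATURE, "toy", "toych", threshold=ThresholdSpec("absolute", 0.5))
    net.ensure_area(CONCEPT, "toyc", "toych", mode=ORDER_INDEPENDENT)
    net.wiring["toy"] = "toyc"
    return net


@pytest.fixture(scope="session")
def trained():
    """Full staged protocol on the default world (two passes per stage)."""
    cfg = RunConfig(seed=1)
    net, report = run_protocol(cfg)
    return net, report
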