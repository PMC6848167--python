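import logging

import pytest

from causalnet import (
    MeasurementSet,
    NodePenaltyWeights,
    PerturbationSet,
    SignedNetwork,
    SolverConfig,
)


@pytest.fixture(autouse=True)
def _quiet_logs():
    logging.disable(logging.WARNING)
    yield
    logging.disable(logging.NOTSET)


@pytest.fixture
def chain_pkn():
    """P -(+)-> A -(+)-> T"""
    return SignedNetwork.from_edges([("P", "A", 1), ("A", "T", 1)])


@pytest.fixture
def diamond_pkn():
    """U fans out to two parallel activating paths ending in T1 / T2."""
    return SignedNetwork.from_edges(
        [("U", "A", 1), ("U", "B", 1), ("A", "T1", 1), ("B", "T2", 1)]
    )


@pytest.fixture
def no_gamma():
    return NodePenaltyWeights()


def make_cfg(**kw):
    defaults = dict(beta=0.1, relgap=0.0, pool_populate=10, pool_capacity=10,
                    time_limit_s=60)
    defaults.update(kw)
    return SolverConfig(**defaults)


@pytest.fixture
def cfg_factory():
    return make_cfg
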