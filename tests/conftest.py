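"""Shared fixtures: a mid-sized synthetic dataset generated once per session."""

import numpy as np
import pytest

from cislnc.qc import lognormalize
from cislnc.synthetic import SyntheticConfig, make_expression, make_genome, make_spatial


@pytest.fixture(scope="session")
def default_cfg():
    return SyntheticConfig(seed=7)


@pytest.fixture(scope="session")
def genome(default_cfg):
    return make_genome(default_cfg)


@pytest.fixture(scope="session")
def expression(genome, default_cfg):
    ann, truth = genome
    return make_expression(ann, truth, default_cfg)


@pytest.fixture(scope="session")
def normalized(expression):
    return lognormalize(expression)


@pytest.fixture(scope="session")
def spatial_bins(genome, default_cfg):
    ann, truth = genome
    return make_spatial(ann, truth, default_cfg)


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
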