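"""Shared fixtures: preset parameter sets and seeded generators."""

import numpy as np
import pytest

from dualtd import ModelParams


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def st_params():
    """Sign-tracker preset: fast TD learning, slow reward recall."""
    return ModelParams(alpha=0.2, eta=0.01)


@pytest.fixture
def gt_params():
    """Goal-tracker preset: slow TD learning, fast reward recall."""
    return ModelParams(alpha=0.01, eta=0.2)
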