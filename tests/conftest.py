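"""Shared fixtures.

``desk_study`` runs the full desk-scale experiment (growing up, four phases,
opposite-field control, 5-seed ensemble) once per session; the end-to-end
acceptance tests all read from it.  Everything else is cheap and local.
"""

import numpy as np
import pytest

from curladapt.controller import init_params
from curladapt.effector import ArmConfig
from curladapt.fixtures import tiny_config
from curladapt.protocol import run_full_study


@pytest.fixture(scope="session")
def arm_cfg():
    return ArmConfig()


@pytest.fixture(scope="session")
def toy_params():
    """A small untrained controller with non-degenerate weights."""
    p = init_params(8, 0)
    rng = np.random.default_rng(42)
    for k in p.weights:
        p.weights[k] = p.weights[k] + 0.05 * rng.standard_normal(p.weights[k].shape)
    return p


@pytest.fixture(scope="session")
def desk_study():
    """Full desk-scale study: main + opposite-field control, 5 seeds."""
    return run_full_study(tiny_config())
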