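"""Shared fixtures: small synthetic sessions and a trained model bundle.

Expensive fixtures are session-scoped; all sizes are chosen so the whole
suite runs in minutes on one core.
"""

from __future__ import annotations

import numpy as np
import pytest

import tremorloop as tl


@pytest.fixture(scope="session")
def base_config():
    return tl.SimConfig(seed=10)


@pytest.fixture(scope="session")
def stim_params():
    return tl.StimParams()


@pytest.fixture(scope="session")
def posture_session(base_config):
    """Stim-off posture session: 4 × 20 s posture blocks, 20 s rests."""
    protocol = tl.make_protocol("posture", 4, 20.0, 20.0)
    return tl.generate_session(base_config, protocol), protocol


@pytest.fixture(scope="session")
def movement_session(base_config):
    protocol = tl.make_protocol("movement", 4, 20.0, 20.0)
    cfg = tl.SimConfig.from_dict({**base_config.to_dict(), "seed": 11})
    return tl.generate_session(cfg, protocol), protocol


@pytest.fixture(scope="session")
def trained(base_config, stim_params):
    """Four-cell model bundle trained on fresh synthetic sessions."""
    bundle, table, cells = tl.train_default_bundle(
        base_config, stim_params, algorithms=("svm", "lr", "lda"), seed=0
    )
    return bundle, table, cells
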