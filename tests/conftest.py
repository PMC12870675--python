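"""Shared fixtures: a small phantom space and reduced-size cohorts.

Session-scoped so the expensive simulations run once; tests must not
mutate fixture objects.
"""

import numpy as np
import pytest

from fndconn.phantom import make_phantom_space
from fndconn.simulate import SimulationConfig, simulate_longitudinal_cohort


@pytest.fixture(scope="session")
def space():
    return make_phantom_space((12, 12, 10), n_networks=7, seed=1)


@pytest.fixture(scope="session")
def small_cohort(space):
    """12 FND (10 with follow-up) + 4 HC at reduced scan length."""
    cfg = SimulationConfig(
        n_fnd=12, n_followup=10, n_hc=4, n_timepoints=80, seed=7
    )
    return simulate_longitudinal_cohort(space, cfg)


@pytest.fixture(scope="session")
def effect_cohort(space):
    """Full-size cohort with a planted baseline effect only (no HCs)."""
    cfg = SimulationConfig(n_hc=0, longitudinal_effect_size=0.0, seed=13)
    return simulate_longitudinal_cohort(space, cfg)


@pytest.fixture
def rng():
    return np.random.default_rng(0)
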