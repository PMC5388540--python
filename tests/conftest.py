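"""Shared fixtures: the standard battery and small synthetic sessions.

Everything is generated programmatically; session-scoped fixtures keep
the rendering and simulation cost to one pass per test run.
"""

from __future__ import annotations

import numpy as np
import pytest

from objcode.simulate import (
    DEFAULT_AREA_PROFILES,
    condition_cell_luminance,
    make_area_population,
    simulate_scenario,
    simulate_session,
)
from objcode.stimuli import build_stimulus_set


@pytest.fixture(scope="session")
def stimset():
    return build_stimulus_set()


@pytest.fixture(scope="session")
def cell_lum(stimset):
    """Per-condition mean luminance on the 6 x 11 RF grid."""
    return condition_cell_luminance(stimset)


@pytest.fixture(scope="session")
def small_scenario(stimset):
    """Four-area scenario, 25 units/area, 26 trials (shared, read-only)."""
    return simulate_scenario(stimset, n_units_per_area=25, n_trials=26, seed=11)


@pytest.fixture(scope="session")
def ll_session(stimset, cell_lum):
    """A small LL-like session used by decoding tests."""
    params = make_area_population(DEFAULT_AREA_PROFILES["LLlike"], 8, seed=3)
    return simulate_session(
        stimset, params, n_trials=26, seed=3, cell_luminance=cell_lum, area="LLlike"
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
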