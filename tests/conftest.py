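"""Shared fixtures: scaled-down phantom parameters for fast unit tests.

Small grids (64–256 px) keep individual tests fast; the statistics the
generator is calibrated to (heights, spreads) do not depend on grid size,
so only the acceptance tests use the full 512-px default geometry.
"""

from dataclasses import replace

import numpy as np
import pytest

from colonyscatter import BAD_PARAMS, GOOD_PARAMS


@pytest.fixture
def small_good_params():
    return replace(
        GOOD_PARAMS, grid_size=128, pixel_pitch=4.0,
        colony_radius_mean=150.0, colony_radius_sd=10.0,
    )


@pytest.fixture
def small_bad_params():
    return replace(
        BAD_PARAMS, grid_size=128, pixel_pitch=4.0,
        colony_radius_mean=150.0, colony_radius_sd=20.0,
        lump_width_range_um=(15.0, 35.0),
    )


@pytest.fixture
def tiny_good_params(small_good_params):
    return replace(small_good_params, grid_size=64, pixel_pitch=8.0)


@pytest.fixture
def tiny_bad_params(small_bad_params):
    return replace(small_bad_params, grid_size=64, pixel_pitch=8.0)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
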