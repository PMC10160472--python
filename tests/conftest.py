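import numpy as np
import pytest

from rootca import (
    DEFAULT_RETENTION,
    DRIVING_PRESETS,
    GrowthConfig,
    SuctionField,
    default_layout,
    wetting_bulb,
)


@pytest.fixture
def table_params():
    """The fitted medium-loam retention constants."""
    return DEFAULT_RETENTION


@pytest.fixture
def boll_log():
    """Logarithmic driving law, boll stage, 30 cm spacing."""
    return DRIVING_PRESETS["boll-30cm"]


@pytest.fixture
def boll_exp():
    """Exponential driving law, boll stage, 15 cm spacing."""
    return DRIVING_PRESETS["boll-15cm"]


@pytest.fixture
def small_field():
    """A 10 x 20 cm suction field with a left-to-right gradient."""
    ncol, nrow = 40, 20
    x = (np.arange(ncol) + 0.5) * 0.5
    vals = np.tile(0.05 + 0.01 * x, (nrow, 1))
    return SuctionField(vals, x_extent=20.0, y_extent=10.0, cell_size=0.5)


@pytest.fixture
def default_scenario(boll_log):
    """Full-size default run inputs: bulb field, 30 cm layout, growth config."""
    return wetting_bulb(), default_layout(30), GrowthConfig(driving=boll_log, rng_seed=7)
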