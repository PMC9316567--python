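import numpy as np
import pandas as pd
import pytest

from cartplot.data_model import ControlBounds
from cartplot.synthetic import SyntheticConfig, generate_coculture, generate_controls


@pytest.fixture(scope="session")
def default_cfg() -> SyntheticConfig:
    """Canonical synthetic study conditions at the suite's fixed seed."""
    return SyntheticConfig(seed=1)


@pytest.fixture(scope="session")
def sim_tables(default_cfg):
    """(control_green, control_red, cocultured, truth) under the default config."""
    cg, cr = generate_controls(default_cfg)
    cc, truth = generate_coculture(default_cfg)
    return cg, cr, cc, truth


@pytest.fixture()
def example_bounds() -> ControlBounds:
    """The worked-example bounds: green in [60, inf), red bleed <= 5,
    red in [70, inf), green bleed <= 4."""
    return ControlBounds(green_lo=60.0, red_bleed_hi=5.0, red_lo=70.0, green_bleed_hi=4.0)


@pytest.fixture()
def small_cells() -> pd.DataFrame:
    """Three valid hand-written cell rows covering all roles."""
    return pd.DataFrame({
        "cell_id": ["a", "b", "c"],
        "experiment_id": ["e1", "e1", "e1"],
        "role": ["control_green", "control_red", "cocultured"],
        "green_raw": [1000.0, 20.0, 800.0],
        "red_raw": [15.0, 1500.0, 400.0],
        "area": [400.0, 900.0, 500.0],
        "perimeter": [75.0, 120.0, 85.0],
        "f5mc": [300.0, 500.0, np.nan],
        "fpi": [1000.0, 1000.0, np.nan],
    })
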