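import dataclasses

import numpy as np
import pytest

from t2dscreen.params import base_parameter_set, load_specs
from t2dscreen.screening import ScreeningStrategy
from t2dscreen.synthetic_data import calibrate_life_table


@pytest.fixture(scope="session")
def specs():
    return load_specs()


@pytest.fixture(scope="session")
def degenerate_specs(specs):
    """All standard errors zeroed: every draw equals the point estimate."""
    return {name: dataclasses.replace(s, se=0.0) for name, s in specs.items()}


@pytest.fixture(scope="session")
def params(specs):
    return base_parameter_set(specs)


@pytest.fixture(scope="session")
def life_table():
    return calibrate_life_table(73.6)


@pytest.fixture(scope="session")
def all_strategies():
    return [ScreeningStrategy(setting=st, interval=iv, start_age=40)
            for iv in ("one-off", "annual", "3-yearly")
            for st in ("CHS", "DHC")]
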