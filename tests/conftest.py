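import numpy as np
import pytest

from iculoop.patient import (
    ConstantResistance,
    make_cohort,
    nominal_params,
)


@pytest.fixture(scope="session")
def pop80():
    """Population-nominal 80-kg patient with flat insulin sensitivity."""
    return nominal_params(80.0, resistance_profile=ConstantResistance(1.0))


@pytest.fixture(scope="session")
def small_cohort():
    return make_cohort(20, seed=42)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
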