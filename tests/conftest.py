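import numpy as np
import pytest

from instabean.models import BoundaryMoistures
from instabean.simulate import RehydrationSimSpec, gen_rehydration_dataset

#: generative moisture window used across fitting tests (%db)
M_O, M_E = 11.0, 150.0


@pytest.fixture
def true_bounds():
    return BoundaryMoistures(m_o=M_O, m_e=M_E)


@pytest.fixture
def weibull_spec():
    """Noiseless four-temperature Weibull study."""
    return RehydrationSimSpec(
        model_name="weibull",
        true_params={"alpha_ref": 4.52, "beta": 0.6},
        e_a=14.0,
        m_o=M_O,
        m_e=M_E,
        noise_sd=0.0,
        seed=0,
    )


@pytest.fixture
def weibull_curves(weibull_spec):
    return gen_rehydration_dataset(weibull_spec)
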