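import numpy as np
import pytest

from cpcphase import ModelParameters, NumericsConfig, OrderParameterField


@pytest.fixture
def water_params() -> ModelParameters:
    """Reference parameters of the zero-IP6 (water) run."""
    return ModelParameters()  # D0=0.01, T=0.8, epsilon=0.1, c=0 -> phi_bar=0.5


@pytest.fixture
def fast_config() -> NumericsConfig:
    """Small, quick integration setup used by most solver tests."""
    return NumericsConfig(N=32, t_end=1.0)


def uniform_field(value: float, N: int = 8, L: float = 1.0) -> OrderParameterField:
    return OrderParameterField(np.full((N, N), value), L=L)


@pytest.fixture
def make_uniform():
    return uniform_field
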