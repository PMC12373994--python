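import numpy as np
import pytest
from hypothesis import settings

from cb1pet.synthetic import FrameSchedule, InputFunctionModel

settings.register_profile("suite", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def input_model():
    """Default ground-truth arterial model."""
    return InputFunctionModel()


@pytest.fixture(scope="session")
def true_input(input_model):
    """Densely sampled metabolite-corrected input (the truth MA1 consumes)."""
    return input_model.to_input_function()


@pytest.fixture(scope="session")
def schedule():
    return FrameSchedule.default()


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)
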