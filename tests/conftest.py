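import numpy as np
import pytest
from hypothesis import settings

from wholecell.biophysics import GHKContext
from wholecell.pipeline import chloride_context
from wholecell.protocols import StepProtocol
from wholecell.solutions import junction_potential_henderson, load_reference_solution

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def pipette_1um():
    return load_reference_solution("pipette_ca_1um")


@pytest.fixture(scope="session")
def bath_standard():
    return load_reference_solution("bath_standard")


@pytest.fixture(scope="session")
def cl_context(pipette_1um, bath_standard) -> GHKContext:
    """GHK context for Cl- under the standard recording solutions."""
    return chloride_context(pipette_1um, bath_standard)


@pytest.fixture(scope="session")
def vlj_standard(pipette_1um, bath_standard) -> float:
    return junction_potential_henderson(pipette_1um, bath_standard)


@pytest.fixture(scope="session")
def step_protocol() -> StepProtocol:
    return StepProtocol()


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(12345)
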