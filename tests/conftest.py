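import numpy as np
import pytest

from ventclear import kinetics
from ventclear.tac_io import FrameSchedule


@pytest.fixture(scope="session")
def schedule() -> FrameSchedule:
    return FrameSchedule.default()


@pytest.fixture(scope="session")
def fine_grid() -> np.ndarray:
    return kinetics.fine_time_grid()


@pytest.fixture(scope="session")
def feng_params() -> kinetics.InputFunctionParams:
    return kinetics.InputFunctionParams()


@pytest.fixture(scope="session")
def feng_curve(fine_grid, feng_params) -> np.ndarray:
    return kinetics.feng_input(feng_params, fine_grid)
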