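import numpy as np
import pytest

from axonmorph import AxonPopulationModel
from axonmorph.invivo import CurrentDensitySeries


@pytest.fixture
def visual_tract_model() -> AxonPopulationModel:
    """Visual transcallosal literature model (θ=0.23, β=0.73)."""
    return AxonPopulationModel.from_params(0.40, 0.23, 0.14, 0.73)


@pytest.fixture
def frontal_tract_model() -> AxonPopulationModel:
    """Frontal transcallosal literature model (θ=0.05, β=0.68)."""
    return AxonPopulationModel.from_params(0.40, 0.05, 0.14, 0.68)


@pytest.fixture
def cd_time_axis() -> np.ndarray:
    """Uniform 1024 Hz time axis from ~-100 ms to ~300 ms."""
    return np.arange(-103, 309) / 1024.0 * 1000.0


@pytest.fixture
def make_cd_series(cd_time_axis):
    """Factory for Gaussian-bump current-density series on the shared axis."""

    def _make(center_ms: float, width_ms: float = 8.0, amplitude: float = 1.0):
        amp = amplitude * np.exp(-0.5 * ((cd_time_axis - center_ms) / width_ms) ** 2)
        return CurrentDensitySeries(cd_time_axis, amp)

    return _make
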