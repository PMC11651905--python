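import pytest

from striderslide import (
    FluidProperties,
    WaveDragModel,
    default_configuration,
    saturating_kernel,
)


@pytest.fixture(scope="session")
def fluid():
    return FluidProperties()


@pytest.fixture(scope="session")
def model():
    """Default wave-drag closure (peaked kernel, calibrated amplitude)."""
    return WaveDragModel()


@pytest.fixture(scope="session")
def saturating_model():
    """Monotone-kernel variant used for monotonicity properties."""
    return WaveDragModel(kernel=saturating_kernel)


@pytest.fixture(scope="session")
def medium_symmetric():
    """Representative medium-sized slider in the symmetric gait."""
    return default_configuration("intermediate", "A_paludum", "symmetric")


@pytest.fixture(scope="session")
def medium_asymmetric():
    return default_configuration("intermediate", "A_paludum", "asymmetric")
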