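import numpy as np
import pytest

from rhizoquant.synthgen import FilamentNetworkParams, make_filament_timelapse


@pytest.fixture(scope="session")
def static_stack():
    """Frozen (remodeling rate 0), noise-free network: the stabilized
    control limit."""
    params = FilamentNetworkParams(remodeling_rate=0.0, noise_sigma=0.0,
                                   n_frames=5, seed=42)
    stack, _ = make_filament_timelapse(params)
    return stack


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
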