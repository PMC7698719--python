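import numpy as np
import pytest

from cemct import phantom as ph


@pytest.fixture
def rat_spec():
    """Noise-free abdomen-like phantom with aorta, muscle and tumor."""
    return ph.default_rat_spec(seed=0, noise_sigma_hu=0.0)


@pytest.fixture
def kinetic_truth():
    """Generating kinetic parameters: tumor (0.24, 11.6%), muscle (0.13, 12.2%)."""
    return ph.KineticGroundTruth(
        regions={"tumor": (0.24, 0.116), "muscle": (0.13, 0.122)})


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
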