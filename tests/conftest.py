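import sys
from pathlib import Path

import pytest

sys.path.insert(0, str(Path(__file__).parent))  # expose tests/_oracles.py

from smolbind.simulate import ForceConfig, MovieConfig


@pytest.fixture
def movie_config():
    """Default-noise movie/trace configuration with a fixed seed."""
    return MovieConfig(seed=123)


@pytest.fixture
def noiseless_movie_config():
    return MovieConfig(seed=123, shot_noise=False)


@pytest.fixture
def clean_force_config():
    """Deterministic force curves: no noise, no drift, no adhesion."""
    return ForceConfig(
        seed=7, noise_sd=0.0, p_nonspecific=0.0,
        baseline_offset_sd=0.0, baseline_slope_sd=0.0,
    )
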