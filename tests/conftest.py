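import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))

from nemaquant import (
    LocomotionSimConfig,
    WormMovieConfig,
    simulate_worm_movie,
)


@pytest.fixture(scope="session")
def small_movie():
    """Fixed-seed 100-frame 64x64 rendered worm movie with ground truth."""
    loc = LocomotionSimConfig(duration=99, seed=7, roam_rate=0.05,
                              dwell_rate=0.05)
    cfg = WormMovieConfig(locomotion=loc)
    return simulate_worm_movie(cfg)


@pytest.fixture
def sinusoid_midline_points():
    x = np.linspace(0.0, 100.0, 200)
    y = 8.0 * np.sin(2 * np.pi * x / 60.0)
    return np.column_stack([x, y])
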