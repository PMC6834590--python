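import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

from wormstate.synthetic import BoutSchedule, SyntheticWormConfig, render_worm_video


@pytest.fixture(scope="session")
def two_bout_video():
    """10-min, 3-fps rendered video with two programmed bouts and its truth."""
    schedule = BoutSchedule(
        intervals=[(120.0, 210.0), (360.0, 480.0)], twitches=[], duration_s=600.0
    )
    config = SyntheticWormConfig(noise_sd=2.0, seed=5)
    video, truth = render_worm_video(config, schedule)
    return config, schedule, video, truth


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
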