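import numpy as np
import pytest

from exertsense import SynthConfig, generate_mvc, generate_task


@pytest.fixture(scope="session")
def small_cfg():
    """A short but structurally complete task configuration."""
    return SynthConfig(seed=7, n_grips=3, grip_duration_s=1.5, gap_duration_s=1.5,
                       lead_in_s=3.0, lead_out_s=3.0)


@pytest.fixture(scope="session")
def small_session(small_cfg):
    task, gt = generate_task(small_cfg)
    mvc = generate_mvc(small_cfg)
    return task, gt, mvc


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
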