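import numpy as np
import pytest

from isoimap import simulate as sim


@pytest.fixture(scope="session")
def cfg_small():
    """Desk-scale simulator config shared by fast unit tests."""
    return sim.SimConfig(
        image_height_px=96, image_width_px=96, n_trials_per_condition=6, seed=11
    )


@pytest.fixture(scope="session")
def gt_small(cfg_small):
    return sim.make_ground_truth(cfg_small)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20230923)
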