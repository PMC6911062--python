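import numpy as np
import pytest

from mossmap import region, synthetic


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)


@pytest.fixture
def small_grid():
    return region.make_grid((0.0, 0.0, 10.0, 10.0), 1.0)


@pytest.fixture(scope="session")
def desk_scenario():
    """One small synthetic study shared by read-only tests."""
    cfg = synthetic.ScenarioConfig(bbox=(0.0, 0.0, 15.0, 15.0), home=(4.0, 8.0),
                                   alpha0=-0.5, forest_threshold=0.3, seed=42)
    return synthetic.gen_scenario(cfg)
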