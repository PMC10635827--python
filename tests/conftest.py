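import numpy as np
import pytest

from steatoscope import synthetic


@pytest.fixture(scope="session")
def default_image():
    """One default-scenario synthetic organoid image (seed 7)."""
    return synthetic.make_organoid_image(synthetic.ImageScenario(seed=7))


@pytest.fixture(scope="session")
def labeling_tables():
    """Default labeling datasets for seeds 1 and 2, with their truths."""
    out = {}
    for seed in (1, 2):
        out[seed] = synthetic.make_isotopologue_dataset(synthetic.LabelingScenario(seed=seed))
    return out


@pytest.fixture(scope="session")
def screen_data():
    return synthetic.make_screen_dataset(synthetic.ScreenScenario(seed=3))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
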