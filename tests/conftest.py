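import numpy as np
import pytest

from eldercare_game import StrategyProfile, make_baseline_parameters


@pytest.fixture
def baseline():
    return make_baseline_parameters()


@pytest.fixture
def center():
    return StrategyProfile(0.5, 0.5, 0.5, 0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)


def random_profile(rng) -> StrategyProfile:
    return StrategyProfile(*rng.uniform(0.0, 1.0, size=4))
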