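import numpy as np
import pytest

from emgfactors.pipeline import compute_features
from emgfactors.simulate import GeneratorConfig

# Reduced design used by the unit tests: three motions (a flexor-dominant
# grip, an extensor-dominant open hand, rest) and short 1.2 s trials, so a
# full campaign stays in the hundreds of milliseconds while keeping the
# 7-windows-per-trial segmentation nontrivial.
SMALL_MOTIONS = ("CH", "OH", "RT")
SMALL_ACTIVATION = (
    (0.6, 0.5, 1.8, 1.6, 0.5, 0.4),
    (1.6, 1.5, 0.5, 0.4, 0.4, 0.5),
    (0.05,) * 6,
)


def small_config(seed=0, **overrides) -> GeneratorConfig:
    base = dict(trial_duration=1.2, motions=SMALL_MOTIONS,
                activation=SMALL_ACTIVATION, seed=seed)
    base.update(overrides)
    return GeneratorConfig(**base)


@pytest.fixture(scope="session")
def small_features():
    """Feature table of one subject under the reduced stressed design."""
    return compute_features(small_config(seed=7), ["sub01"])


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
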