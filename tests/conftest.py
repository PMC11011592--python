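import numpy as np
import pytest

from dfcb import synthetic
from dfcb.io import PipelineConfig


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def tiny_spec():
    """Small, fast cohort spec for pipeline plumbing tests."""
    return synthetic.SyntheticSpec(
        n_per_group=6, R=8, N=80, planted_edges=((1, 2),),
        modulation_period=20.0, effect_amplitude=0.6, noise_sd=0.3, seed=11,
    )


@pytest.fixture(scope="session")
def tiny_cohort(tiny_spec):
    return synthetic.generate_cohort(tiny_spec)


@pytest.fixture
def tiny_config():
    return PipelineConfig(
        window_lengths=[20], step_sizes=[5], cv_folds=3, cv_repeats=2, rng_seed=3,
    )
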