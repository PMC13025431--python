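import numpy as np
import pytest

from raycens.model import CensoredSample, CensoringModel, sample_censored


@pytest.fixture
def toy_sample() -> CensoredSample:
    """Four observations, three failures; every statistic is hand-computable."""
    return CensoredSample(
        y=np.array([1.0, 1.5, 2.0, 2.5]), d=np.array([1, 0, 1, 1])
    )


@pytest.fixture
def base_model() -> CensoringModel:
    """The workhorse configuration (mu, sigma, gamma) = (0.5, 1, 1)."""
    return CensoringModel(0.5, 1.0, 1.0)


@pytest.fixture
def medium_sample(base_model) -> CensoredSample:
    return sample_censored(base_model, 100, seed=20260920)
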