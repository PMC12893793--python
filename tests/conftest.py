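import numpy as np
import pytest

import popax


@pytest.fixture(scope="session")
def random_model_dataset():
    """Random encoding model: uncorrelated per-cell sensitivities."""
    pop = popax.make_population(400, dmu_rho=0.0, seed=11)
    return popax.sample_trials(pop, 50, seed=12)


@pytest.fixture(scope="session")
def shared_model_dataset():
    """Shared encoding model: perfectly correlated sensitivities."""
    pop = popax.make_population(400, dmu_rho=1.0, seed=11)
    return popax.sample_trials(pop, 50, seed=12)


@pytest.fixture(scope="session")
def gaussian_pair():
    """Two 30-cell Gaussian response clouds with a known mean shift."""
    rng = np.random.default_rng(7)
    mu = rng.uniform(0.5, 1.5, 30)
    shift = rng.normal(0.0, 0.3, 30)
    a = mu[:, None] + 0.3 * rng.standard_normal((30, 60))
    b = (mu + shift)[:, None] + 0.3 * rng.standard_normal((30, 60))
    return a, b


def lum_pair(responses, **fixed):
    """(scotopic, photopic) cells x trials arrays at a fixed grid setting."""
    return (
        responses.single(luminance="scotopic", **fixed),
        responses.single(luminance="photopic", **fixed),
    )


def ori_pair(responses, **fixed):
    a = responses.single(orientation_deg=0.0, **fixed)
    b = responses.single(orientation_deg=45.0, **fixed)
    return a, b


@pytest.fixture(scope="session")
def helpers():
    class H:
        lum_pair = staticmethod(lum_pair)
        ori_pair = staticmethod(ori_pair)

    return H
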