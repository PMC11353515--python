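import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_lg_observations(model, T, seed):
    """Simulate a truth path and observations from the scalar LG model."""
    r = np.random.default_rng(seed)
    x = model.prior_mean + np.sqrt(model.prior_var) * r.standard_normal()
    xs, ys = [], []
    for _ in range(T):
        x = model.a * x + model.b * r.standard_normal()
        xs.append(x)
        ys.append(model.c * x + model.d * r.standard_normal())
    return np.array(xs), np.array(ys)
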