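import numpy as np
import pytest

from graphsig import ObservationBundle, build_local_graph, default_epsilon


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_bundle(rng):
    def _make(m=5, d=8, scale=1.0, seed=None):
        gen = rng if seed is None else np.random.default_rng(seed)
        return ObservationBundle(features=scale * gen.normal(size=(m, d)))

    return _make


@pytest.fixture
def make_graph(make_bundle):
    def _make(m=5, d=8, seed=None, epsilon=None):
        bundle = make_bundle(m=m, d=d, seed=seed)
        eps = epsilon if epsilon is not None else default_epsilon(bundle)
        return build_local_graph(bundle, eps)

    return _make
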