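import numpy as np
import pytest

from vcshare.fixtures import FixtureSpec, make_fixture


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def gradient64():
    return make_fixture(FixtureSpec(kind="gradient", shape=(64, 64), seed=1))


@pytest.fixture
def covers64():
    return (
        make_fixture(FixtureSpec(kind="blobs", shape=(64, 64), seed=2)),
        make_fixture(FixtureSpec(kind="text", shape=(64, 64), seed=3)),
    )
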