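import numpy as np
import pytest

from laterkit import RecinormalParams, make_fixture_suite, simulate_later


@pytest.fixture(scope="session")
def fixture_suite():
    """Canonical synthetic event streams (swivel/shift/null/early/quantized)."""
    return make_fixture_suite(seed=11)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def swivel_pair():
    """Large two-condition sample generated under an exact swivel (ratio 2/3)."""
    pre = simulate_later(RecinormalParams(3.0, 0.4), 2000, seed=101)
    stim = simulate_later(RecinormalParams(4.5, 0.6), 2000, seed=202)
    return pre, stim
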