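import numpy as np
import pytest

from pnss import PhantomSpec, make_phantom


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def phantom():
    """Default 128x128 phantom fixture (seed 7, texture + streak probes)."""
    return make_phantom(PhantomSpec())


@pytest.fixture(scope="session")
def pc_phantom():
    """Strictly piecewise-constant 128x128 phantom (no texture, no streaks)."""
    return make_phantom(
        PhantomSpec(include_texture=False, include_streak_proxy=False)
    )
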