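import numpy as np
import pytest

from cellagg.engine import AbmConfig, FluxSpec
from cellagg.space import BoxSpec


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def box100():
    return BoxSpec(side_length=100.0)


@pytest.fixture
def small_config():
    """Fast F98-like configuration in a reduced box (density preserved)."""
    return AbmConfig(
        n_initial=64,
        cell_diameter=13.2,
        step_length=0.658 * 6,
        proliferation_rate=0.0,
        alpha_max=0.7,
        flux=FluxSpec(enabled=False),
        box=BoxSpec(side_length=240.64),
        n_iterations=60,
        seed=7,
    )
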