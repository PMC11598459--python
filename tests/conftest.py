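import numpy as np
import pytest

from sweatsense import GlandParams, build_layout


@pytest.fixture
def layout_d():
    return build_layout("D", t_cycle=0.5)


@pytest.fixture
def layout_g():
    return build_layout("G", t_cycle=0.5)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def medium_params():
    """Medium sweat rate: 3.5 droplets per active period on average."""
    return GlandParams(srg=0.7)
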