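import math
from dataclasses import replace

import pytest

from cassleaf import synth
from cassleaf.fvcb import PhotoParams
from cassleaf.simulator import Environment


@pytest.fixture(scope="session")
def mean_params() -> PhotoParams:
    """Cultivar-mean biochemical parameters."""
    return PhotoParams(vcmax25=105.0, jmax25=165.0, tpu25=10.8, rd25=1.5)


@pytest.fixture(scope="session")
def env() -> Environment:
    return Environment()


@pytest.fixture(scope="session")
def fast_preset():
    return synth.make_preset("fast")


@pytest.fixture(scope="session")
def slow_preset():
    return synth.make_preset("slow")


@pytest.fixture(scope="session")
def fast_steady_preset(fast_preset):
    """Fast preset with exponential (phase-target) conductance dynamics."""
    return replace(fast_preset, gs_coupling="steady")


@pytest.fixture(scope="session")
def infinite_gm_preset():
    """Cultivar preset with no mesophyll resistance (Ci == Cc)."""
    return replace(synth.make_preset("TME693"), gm=math.inf)


@pytest.fixture(scope="session")
def noiseless():
    return synth.NOISELESS
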