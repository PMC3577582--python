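import numpy as np
import pytest

from fourcurrent.params import builtin_set, builtin_set_names
from fourcurrent.protocols import find_stimulus_threshold

SET_NAMES = builtin_set_names()


@pytest.fixture(scope="session")
def all_sets():
    return {name: builtin_set(name) for name in SET_NAMES}


@pytest.fixture(scope="session")
def epi():
    return builtin_set("epi")


@pytest.fixture(scope="session")
def lrd():
    return builtin_set("lrd")


@pytest.fixture(scope="session")
def tnnp():
    return builtin_set("tnnp")


@pytest.fixture(scope="session")
def thresholds(all_sets):
    """1-ms stimulation threshold per built-in set (cached per session)."""
    return {name: find_stimulus_threshold(p) for name, p in all_sets.items()}


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(20260928)
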