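import time

import numpy as np
import pytest

from lgrbsn.model import LGRBSN, PipelineConfig
from lgrbsn.phantom import make_gyrus_phantom, make_recovery_case


@pytest.fixture(scope="session")
def phantom_aligned():
    return make_gyrus_phantom(misalignment="aligned")


@pytest.fixture(scope="session")
def phantom_misaligned():
    return make_gyrus_phantom(misalignment="misaligned")


def _timed_fit(phantom):
    t0 = time.perf_counter()
    result = LGRBSN.from_phantom(phantom, PipelineConfig()).fit()
    return result, time.perf_counter() - t0


@pytest.fixture(scope="session")
def result_aligned(phantom_aligned):
    """Full pipeline on the aligned phantom (shared across tests; ~1-2 min)."""
    return _timed_fit(phantom_aligned)


@pytest.fixture(scope="session")
def result_misaligned(phantom_misaligned):
    return _timed_fit(phantom_misaligned)


@pytest.fixture(scope="session")
def recovery_fit():
    """Ground-truth recovery fixture: phantom warped by a known field, then fitted."""
    phantom, known = make_recovery_case(seed=7)
    result, elapsed = _timed_fit(phantom)
    return phantom, known, result, elapsed


@pytest.fixture
def rng():
    return np.random.default_rng(1234)
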