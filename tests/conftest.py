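import logging

import numpy as np
import pytest

from cloneboot import ReadCountTable


@pytest.fixture(autouse=True)
def _quiet_warnings(caplog):
    # warnings are part of several contracts; keep them captured, not printed
    logging.getLogger("cloneboot").setLevel(logging.WARNING)
    yield


@pytest.fixture
def small_counts() -> ReadCountTable:
    """Two samples, three SNVs, unambiguous nested clones."""
    return ReadCountTable(
        ["S1", "S2"],
        ["s1", "s2", "s3"],
        ref=np.array([[50, 60, 90], [40, 80, 70]]),
        alt=np.array([[50, 40, 10], [60, 20, 30]]),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
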