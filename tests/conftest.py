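import numpy as np
import pandas as pd
import pytest

from poissonplus import LinearProxyFit


@pytest.fixture
def rng():
    return np.random.default_rng(20260930)


@pytest.fixture
def reference_fit():
    """The reference ROX-on-volume proxy line R = 4454.4 v - 541."""
    return LinearProxyFit(slope=4454.4, intercept=-541.0, r=0.81)


def make_chip(n_rows, n_cols, calls, rox):
    """Build a chip table from flat call/rox vectors (row-major order)."""
    n = n_rows * n_cols
    assert len(calls) == n and len(rox) == n
    rows, cols = np.divmod(np.arange(n), n_cols)
    return pd.DataFrame({"row": rows, "col": cols, "rox": rox, "call": calls})


@pytest.fixture
def make_chip_table():
    return make_chip
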