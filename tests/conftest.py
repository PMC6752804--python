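import numpy as np
import pytest

from trajsig.sigcore import LabeledPath


@pytest.fixture
def fig_path():
    """The 5-point 2-channel worked-example path (X1, X2)."""
    return LabeledPath(
        times=np.arange(5, dtype=float),
        values=np.column_stack([[2, 4, 6, 8, 10], [1, 2, 8, 9, 10]]).astype(float),
        channel_names=("X1", "X2"),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(20240917)
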