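import numpy as np
import pandas as pd
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(20240915)


@pytest.fixture
def small_expression():
    """Tiny strictly positive 2-sample expression matrix."""
    return pd.DataFrame(
        {"S1": [1.0, 2.0, 4.0, 8.0], "S2": [2.0, 4.0, 8.0, 16.0]},
        index=pd.Index(["t1", "t2", "t3", "t4"], name="transcript_id"),
    )
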