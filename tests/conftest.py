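import numpy as np
import pandas as pd
import pytest

from corrcascade.empirical_null import NullConfig, NullThresholds


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def small_expr(rng):
    """10 genes x 12 samples of iid noise around a log2-ish baseline."""
    genes = [f"G{i}" for i in range(10)]
    samples = [f"S{i}" for i in range(12)]
    return pd.DataFrame(7 + rng.standard_normal((10, 12)),
                        index=genes, columns=samples)


@pytest.fixture
def published_thresholds():
    """Fixed cutoffs matching the reference study's printed values."""
    return NullThresholds(-0.379, 0.428, np.linspace(-0.9, 0.9, 101),
                          NullConfig(seed=0))


@pytest.fixture
def two_group_sheet(small_expr):
    return pd.Series(["tumor"] * 6 + ["normal"] * 6, index=small_expr.columns)
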