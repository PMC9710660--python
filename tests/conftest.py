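import numpy as np
import pandas as pd
import pytest

from flexdot import DotTable, FactorKind


@pytest.fixture
def tiny_table() -> DotTable:
    """2 x-levels × 2 y-levels, one quantitative + one qualitative factor."""
    data = pd.DataFrame(
        {
            "gene": ["g1", "g1", "g2", "g2"],
            "cluster": ["c1", "c2", "c1", "c2"],
            "pct": [10.0, 90.0, 55.0, 0.0],
            "status": ["gain", "loss", "neutral", "gain"],
        }
    )
    return DotTable(
        x_name="gene",
        y_name="cluster",
        data=data,
        factor_kinds={
            "pct": FactorKind.QUANTITATIVE,
            "status": FactorKind.QUALITATIVE,
        },
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(42)
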