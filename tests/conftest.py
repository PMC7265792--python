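import numpy as np
import pandas as pd
import pytest

from modnet.types import ExpressionMatrix


@pytest.fixture
def small_expression() -> ExpressionMatrix:
    """3 genes × 4 samples with distinct variances."""
    data = pd.DataFrame(
        [[1.0, 2.0, 3.0, 4.0],
         [0.5, 0.5, 0.6, 0.4],
         [10.0, -10.0, 10.0, -10.0]],
        index=["g1", "g2", "g3"],
        columns=["s1", "s2", "s3", "s4"],
    )
    return ExpressionMatrix(data)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_matrix(values, genes=None, samples=None) -> ExpressionMatrix:
    values = np.asarray(values, dtype=float)
    genes = genes or [f"g{i + 1}" for i in range(values.shape[0])]
    samples = samples or [f"s{i + 1}" for i in range(values.shape[1])]
    return ExpressionMatrix(pd.DataFrame(values, index=genes, columns=samples))
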