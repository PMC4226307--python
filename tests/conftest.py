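import numpy as np
import pandas as pd
import pytest

from wntstrat.io import ExpressionMatrix


@pytest.fixture
def tiny_matrix() -> ExpressionMatrix:
    """3 genes x 2 samples with known values."""
    df = pd.DataFrame({"s1": [1.0, 2.0, 3.0], "s2": [4.0, 5.0, 6.0]},
                      index=["CTNNB1", "FZD7", "MYC"])
    return ExpressionMatrix(df, cohort_id="tiny", scale="log2")


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240901)


def random_matrix(rng, n_genes=50, n_samples=6, cohort_id="rand") -> ExpressionMatrix:
    df = pd.DataFrame(rng.standard_normal((n_genes, n_samples)),
                      index=[f"G{i:03d}" for i in range(n_genes)],
                      columns=[f"s{j}" for j in range(n_samples)])
    return ExpressionMatrix(df, cohort_id=cohort_id, scale="log2")
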