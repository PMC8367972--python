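import numpy as np
import pandas as pd
import pytest

from refstab import CqMatrix, ExpressionMatrix


@pytest.fixture
def small_matrix() -> ExpressionMatrix:
    """3 genes x 4 samples, two tissues; one constant gene, one variable."""
    values = pd.DataFrame(
        {
            "s1": [200.0, 150.0, 10.0],
            "s2": [200.0, 180.0, 12.0],
            "s3": [200.0, 90.0, 400.0],
            "s4": [200.0, 110.0, 380.0],
        },
        index=["const", "wobbly", "specific"],
    )
    tissues = {"s1": "leaf", "s2": "leaf", "s3": "root", "s4": "root"}
    return ExpressionMatrix(values, tissues)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)


def make_cq(values: dict[str, list[float]], groups: dict[str, str]) -> CqMatrix:
    df = pd.DataFrame(values).T
    df.columns = list(groups)
    return CqMatrix(df, groups)


@pytest.fixture
def toy_cq() -> CqMatrix:
    """4 genes x 6 samples in 2 groups; 'drift' has a group-specific shift."""
    groups = {f"s{i}": ("g1" if i <= 3 else "g2") for i in range(1, 7)}
    values = {
        "alpha": [20.0, 20.1, 19.9, 20.2, 20.0, 19.8],
        "beta": [22.0, 22.2, 21.9, 22.1, 22.0, 22.1],
        "gamma": [18.5, 18.4, 18.6, 18.5, 18.3, 18.6],
        "drift": [20.0, 20.1, 19.9, 24.0, 24.2, 23.9],
    }
    return make_cq(values, groups)
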