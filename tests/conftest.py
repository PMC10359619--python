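import sys
from pathlib import Path

import numpy as np
import pandas as pd
import pytest

from coexnet.core_data import ExpressionDataset

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable


@pytest.fixture
def small_csv(tmp_path):
    """3 samples x 2 features expression CSV."""
    path = tmp_path / "expr.csv"
    path.write_text("id,g1,g2\ns1,1.0,4.0\ns2,2.0,5.0\ns3,3.0,6.0\n")
    return path


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def make_dataset(X: np.ndarray, sample_meta: pd.DataFrame | None = None) -> ExpressionDataset:
    n, p = X.shape
    return ExpressionDataset(
        matrix=pd.DataFrame(
            X,
            index=[f"s{i+1}" for i in range(n)],
            columns=[f"g{j+1}" for j in range(p)],
        ),
        sample_meta=sample_meta,
    )


@pytest.fixture
def random_dataset(rng):
    return make_dataset(rng.standard_normal((30, 15)))
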