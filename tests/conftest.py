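import numpy as np
import pandas as pd
import pytest

from qsarnet import DescriptorTable


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def make_table(X, y, ids=None, names=None, activity_name="activity"):
    """Build a DescriptorTable from raw arrays with generated IDs/names."""
    X = np.asarray(X, dtype=float)
    m, n = X.shape
    ids = ids or [f"C{i + 1:04d}" for i in range(m)]
    names = names or [f"d{j + 1:03d}" for j in range(n)]
    desc = pd.DataFrame(X, index=pd.Index(ids, name="compound_id"), columns=names)
    return DescriptorTable(
        desc, pd.Series(np.asarray(y, dtype=float), index=desc.index,
                        name=activity_name),
        activity_name=activity_name,
    )


@pytest.fixture
def random_table(rng):
    X = rng.standard_normal((30, 4))
    y = X[:, 0] - 2 * X[:, 1] + 0.1 * rng.standard_normal(30)
    return make_table(X, y)
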