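import sys
from pathlib import Path

import numpy as np
import pytest

sys.path.insert(0, str(Path(__file__).parent))  # make oracles importable

from fsmlknn import FeatureTable, LabelTable


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def random_tables(rng, n=8, p=4, q=3, prefix=""):
    """A random aligned feature/label table pair (every label gets >= 1 positive)."""
    X = rng.integers(0, 2, (n, p)).astype(np.int8)
    while True:
        Y = rng.integers(0, 2, (n, q)).astype(np.int8)
        if (Y.sum(axis=0) > 0).all():
            break
    drugs = [f"{prefix}drug{i}" for i in range(n)]
    ft = FeatureTable(drugs, [f"{prefix}dim{j}" for j in range(p)], X, "feat")
    lt = LabelTable(drugs, [f"{prefix}lab{l}" for l in range(q)], Y)
    return ft, lt
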