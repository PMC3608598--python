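import numpy as np
import pytest

from metalinprog.io_tables import CountTable, LabelSet


@pytest.fixture
def tiny_counts() -> CountTable:
    return CountTable(
        samples=["s1", "s2", "s3"],
        features=["fA", "fB"],
        counts=np.array([[2, 3], [0, 5], [1, 1]]),
    )


@pytest.fixture
def tiny_labels() -> LabelSet:
    return LabelSet(sample_ids=["s1", "s2", "s3"], labels=["A", "B", "A"])


def random_binary_instance(rng, n=None, m=None, scale=1.0):
    """A small random +/-1-labelled dataset with both classes present."""
    n = n or int(rng.integers(4, 9))
    m = m or int(rng.integers(1, 4))
    Xt = rng.normal(0, scale, size=(n, m))
    y = np.ones(n)
    y[: n // 2] = -1
    rng.shuffle(y)
    return Xt, y
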