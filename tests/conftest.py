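import numpy as np
import pytest

from isingml.datasets import LabeledDataset
from isingml.encoder import IsingProblem


def random_problem(rng: np.random.Generator, d: int) -> IsingProblem:
    """Unstructured random Ising instance (M=d, K=2 bookkeeping)."""
    linear = rng.standard_normal(d)
    quadratic = np.triu(rng.standard_normal((d, d)), 1)
    return IsingProblem(linear, quadratic, offset=float(rng.standard_normal()),
                        n_features=d, n_classes=2)


def random_dataset(rng: np.random.Generator, n: int, m: int, k: int) -> LabeledDataset:
    labels = np.concatenate([np.arange(1, k + 1), rng.integers(1, k + 1, max(n - k, 0))])
    rng.shuffle(labels)
    return LabeledDataset(rng.standard_normal((n, m)), labels[:n], k)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)
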