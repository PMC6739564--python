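import numpy as np
import pytest

from nlsp import MultiLabelDataset, SyntheticSpec, generate_dataset


def make_dataset(labels_rows, n_features=2, seed=0, label_names=None):
    """Small hand-specified dataset from a list of 0/1 label rows."""
    Y = np.asarray(labels_rows, dtype=np.int8)
    if label_names is None:
        label_names = [chr(ord("A") + i) for i in range(Y.shape[1])]
    rng = np.random.default_rng(seed)
    X = rng.random((Y.shape[0], n_features))
    return MultiLabelDataset(
        features=X,
        labels=Y,
        label_names=label_names,
        sample_ids=[f"s{i}" for i in range(Y.shape[0])],
    )


def random_dataset(rng, n, m, d=3):
    """Random valid dataset (every row keeps at least one label)."""
    Y = (rng.random((n, m)) < 0.4).astype(np.int8)
    for i in np.flatnonzero(Y.sum(axis=1) == 0):
        Y[i, rng.integers(m)] = 1
    return make_dataset(Y, n_features=d, seed=int(rng.integers(2**31)))


@pytest.fixture(scope="session")
def strong_signal_dataset():
    """The standard strong-signal scenario: 600 samples, two planted
    blocks of 7 labels, tight feature signal."""
    return generate_dataset(SyntheticSpec(n_samples=600, seed=42))


@pytest.fixture(scope="session")
def planted_blocks():
    spec = SyntheticSpec(n_samples=10, seed=0)
    return [set(b) for b in spec.planted_communities]
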