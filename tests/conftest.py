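import numpy as np
import pytest

from hfia import LabeledDataset, SyntheticSpec, make_dataset


@pytest.fixture
def tiny_dataset() -> LabeledDataset:
    """4 samples x 2 features, two classes; feature 0 is the hand example."""
    return LabeledDataset(
        matrix=np.array([[1.0, 5.0], [2.0, 5.0], [3.0, 5.0], [4.0, 5.0]]),
        labels=("A", "A", "B", "B"),
        feature_names=("g1", "g2"),
    )


@pytest.fixture
def small_planted():
    """40 samples x 200 features, 5 informative at shift 3 — quick to search."""
    spec = SyntheticSpec(n_samples=40, n_features=200, n_informative=5,
                         n_classes=2, mean_shift=3.0, seed=11)
    return make_dataset(spec)


def random_dataset(rng: np.random.Generator, n: int, q: int, c: int
                   ) -> LabeledDataset:
    """A random dense dataset with every class represented at least once."""
    labels = np.concatenate([np.arange(c), rng.integers(0, c, n - c)])
    rng.shuffle(labels)
    return LabeledDataset(
        matrix=rng.normal(size=(n, q)),
        labels=tuple(f"c{k}" for k in labels),
        feature_names=tuple(f"f{j}" for j in range(q)),
    )
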