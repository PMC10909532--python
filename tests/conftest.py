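import numpy as np
import pytest

from hypnagree import HypnogramSet
from hypnagree.stages import label_to_code


def hset_from_labels(rows: list[list[str]], **kwargs) -> HypnogramSet:
    """Build a HypnogramSet from lists of stage labels (test convenience)."""
    codes = np.array([[label_to_code(c) for c in row] for row in rows])
    kwargs.setdefault("subject_id", "test")
    return HypnogramSet(stages=codes, **kwargs)


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_hset() -> HypnogramSet:
    """3 scorers x 6 epochs, already preprocessed (no U/A, trimmed)."""
    return hset_from_labels(
        [
            ["N1", "N2", "N2", "N3", "R", "W"],
            ["N1", "N2", "N3", "N3", "R", "W"],
            ["W", "N2", "N2", "N3", "R", "N1"],
        ]
    )


def random_counts(rng, n_epochs: int, n_raters: int, n_stages: int = 5) -> np.ndarray:
    """Random vote-count matrix with constant row sums."""
    labels = rng.integers(0, n_stages, size=(n_raters, n_epochs))
    counts = np.zeros((n_epochs, n_stages), dtype=np.int64)
    for k in range(n_stages):
        counts[:, k] = (labels == k).sum(axis=0)
    return counts
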