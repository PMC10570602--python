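import numpy as np
import pytest

from lassonet_rnn.data import TimeSeriesDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """Fully observed labeled panel: 12 subjects, 3 waves, 4 features."""
    values = rng.normal(size=(12, 3, 4))
    labels = np.array([0, 1] * 6)
    return TimeSeriesDataset(
        values=values,
        mask=np.ones_like(values, dtype=bool),
        feature_names=("a", "b", "c", "d"),
        time_labels=(2013, 2015, 2018),
        labels=labels,
        subject_ids=tuple(range(12)),
    )


def random_dataset(rng, n=8, q=3, m=5, labeled=True, missing_rate=0.0):
    values = rng.normal(size=(n, q, m))
    mask = rng.random((n, q, m)) >= missing_rate
    labels = rng.integers(0, 2, n) if labeled else None
    return TimeSeriesDataset(
        values=values,
        mask=mask,
        feature_names=tuple(f"f{j}" for j in range(m)),
        time_labels=tuple(range(q)),
        labels=labels,
    )
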