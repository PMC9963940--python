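import numpy as np
import pytest

from ewmcd.stream_core import AdaptedWindow, Chunk, Instance


def chunk_from_arrays(index, X, y):
    """Build a raw Chunk from a feature matrix and 0/1 label vector."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    return Chunk(
        index=index,
        instances=tuple(
            Instance(features=X[i], label=int(y[i]), time_moment=index)
            for i in range(X.shape[0])
        ),
    )


def window_from_instances(index, instances):
    return AdaptedWindow(index=index, instances=tuple(instances))


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def make_chunk():
    return chunk_from_arrays
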