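import numpy as np
import pytest

from cysgan.volumes_io import InstanceLabels


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def two_cubes_touching():
    """Two 4^3 cubes sharing a face."""
    lbl = np.zeros((12, 12, 12), dtype=np.int32)
    lbl[4:8, 4:8, 2:6] = 1
    lbl[4:8, 4:8, 6:10] = 2
    return InstanceLabels(lbl)


@pytest.fixture
def separated_cubes():
    """Three cubes pairwise >= 2 voxels apart."""
    lbl = np.zeros((20, 20, 20), dtype=np.int32)
    lbl[2:7, 2:7, 2:7] = 1
    lbl[2:7, 12:17, 12:17] = 2
    lbl[12:17, 4:9, 4:9] = 3
    return InstanceLabels(lbl)


def random_blob_labels(shape, n_instances, rng, min_size=2):
    """Random non-overlapping rectangular instances for metric tests."""
    lbl = np.zeros(shape, dtype=np.int32)
    placed = 0
    tries = 0
    while placed < n_instances and tries < 200:
        tries += 1
        size = rng.integers(min_size, max(min_size + 1, min(shape) // 2),
                            size=3)
        lo = [int(rng.integers(0, s - sz + 1))
              for s, sz in zip(shape, size)]
        sl = tuple(slice(l, l + int(sz)) for l, sz in zip(lo, size))
        if (lbl[sl] != 0).any():
            continue
        placed += 1
        lbl[sl] = placed
    return InstanceLabels(lbl)
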