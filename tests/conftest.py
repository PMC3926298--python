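import numpy as np
import pytest

from nnsym import PointPattern, nearest_neighbors


@pytest.fixture
def collinear3():
    """Three collinear points A, B, A at x = 0, 1, 2."""
    return PointPattern(coords=[[0, 0], [1, 0], [2, 0]], labels=list("ABA"))


@pytest.fixture
def corners():
    """Unit-square corners labeled A, A, B, B."""
    return PointPattern(coords=[[0, 0], [1, 0], [0, 1], [1, 1]],
                        labels=list("AABB"))


@pytest.fixture
def rng():
    return np.random.default_rng(20240901)


def random_pattern(rng, n, k=2):
    """Random uniform pattern with a random positive class split."""
    coords = rng.uniform(size=(n, 2))
    cuts = np.sort(rng.choice(np.arange(1, n), size=k - 1, replace=False))
    sizes = np.diff(np.concatenate([[0], cuts, [n]]))
    labels = np.repeat([chr(65 + i) for i in range(k)], sizes)
    return PointPattern(coords=coords, labels=rng.permutation(labels))


@pytest.fixture
def make_pattern(rng):
    return lambda n, k=2: random_pattern(rng, n, k)
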