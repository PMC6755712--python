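import numpy as np
import pytest

from nbcfdti import InteractionMatrix


@pytest.fixture
def toy():
    """3x3 network with hand-checkable similarities.

    Drug profiles (columns): d1 = (1,0,1), d2 = (1,1,0), d3 = (0,1,0).
    """
    y = np.array([[1, 1, 0], [0, 1, 1], [1, 0, 0]])
    return InteractionMatrix(y, ("T1", "T2", "T3"), ("d1", "d2", "d3"))


def random_interactions(rng: np.random.Generator, m: int, n: int, density: float = 0.3,
                        ensure_link: bool = True) -> InteractionMatrix:
    values = (rng.random((m, n)) < density).astype(np.int8)
    if ensure_link and values.sum() == 0:
        values[rng.integers(m), rng.integers(n)] = 1
    return InteractionMatrix(
        values,
        tuple(f"T{i}" for i in range(m)),
        tuple(f"D{j}" for j in range(n)),
    )
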