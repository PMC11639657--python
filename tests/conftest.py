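import numpy as np
import pytest

from clustrank import build_design, make_scheme


def random_design(rng, d=None, max_clusters=5, max_m=4, tie_prob=0.5, min_clusters=2):
    """Small random clustered design; mixes tied integer codes and continuous values."""
    d = int(d if d is not None else rng.integers(2, 5))
    rows = []
    for i in range(d):
        n_i = int(rng.integers(min_clusters, max_clusters + 1))
        for j in range(n_i):
            m = int(rng.integers(1, max_m + 1))
            for _ in range(m):
                if rng.random() < tie_prob:
                    v = float(rng.integers(0, 6))
                else:
                    v = float(rng.normal())
                rows.append((f"g{i}", f"c{j}", v))
    return build_design(rows)


@pytest.fixture
def toy_design():
    """d=2; group 1 holds one cluster (1, 3), group 2 one cluster (4)."""
    return build_design([("g1", "c1", 1.0), ("g1", "c1", 3.0), ("g2", "c1", 4.0)])


@pytest.fixture
def rng():
    return np.random.default_rng(20240101)
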