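import numpy as np
import pandas as pd
import pytest

from holo.asv_processing import AsvTable
from holo.distance import DistanceMatrix


@pytest.fixture
def rng():
    return np.random.default_rng(42)


def random_distance_matrix(rng, n, labels=None):
    """Random Euclidean-embeddable distance matrix."""
    pts = rng.normal(size=(n, 3))
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    labels = labels or [f"s{i}" for i in range(n)]
    return DistanceMatrix(d, labels)


def make_table(counts, samples=None, asvs=None, colony_map=None):
    counts = np.asarray(counts)
    samples = samples or [f"s{i}" for i in range(counts.shape[0])]
    asvs = asvs or [f"a{j}" for j in range(counts.shape[1])]
    df = pd.DataFrame(counts, index=samples, columns=asvs)
    cmap = pd.Series(colony_map, index=samples) if colony_map is not None else None
    return AsvTable(df, colony_map=cmap)
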