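import numpy as np
import pytest

from dmnull import CommunityMatrix


@pytest.fixture
def toy_matrix() -> CommunityMatrix:
    """Small hand-checkable 4-host x 3-species table."""
    return CommunityMatrix(
        host_ids=["w1", "w2", "w3", "w4"],
        lineage=["N2", "N2", "daf-2", "daf-2"],
        species_names=["MYb71", "MYb27", "MYb53"],
        counts=[[10, 5, 1], [8, 0, 2], [100, 40, 0], [60, 30, 10]],
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)


def make_matrix(counts, lineage="N2", species=None) -> CommunityMatrix:
    counts = np.asarray(counts)
    n, k = counts.shape
    species = species or [f"sp{j}" for j in range(k)]
    lineages = [lineage] * n if isinstance(lineage, str) else list(lineage)
    return CommunityMatrix(
        [f"h{i}" for i in range(n)], lineages, species, counts
    )
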