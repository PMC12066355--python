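import numpy as np
import pytest

from hybridbarriers.ancestry_core import AncestryMatrix, MarkerMap
from hybridbarriers.synthetic_data import ClusterModel, default_genome


@pytest.fixture(scope="session")
def small_genome() -> MarkerMap:
    """4 chromosomes x 2 Mb x 1 Morgan, 40 evenly spaced markers each."""
    return default_genome(
        n_chromosomes=4, chrom_bp=2_000_000, chrom_morgans=1.0, markers_per_chrom=40
    )


@pytest.fixture(scope="session")
def printed_clusters() -> ClusterModel:
    """The observed bimodal cluster parameters."""
    return ClusterModel()


@pytest.fixture
def tiny_matrix() -> AncestryMatrix:
    """4 individuals x 6 markers on 2 chromosomes, with missing calls."""
    mm = MarkerMap(
        chroms=("chr1", "chr2"),
        chrom_index=np.array([0, 0, 0, 1, 1, 1]),
        pos=np.array([100, 200, 300, 100, 200, 300]),
        length_bp=np.array([1000, 1000]),
        length_morgans=np.array([1.0, 1.0]),
    )
    calls = np.array(
        [
            [0, 1, 2, -1, 0, 1],
            [1, 1, -1, 2, 2, 2],
            [2, 1, 0, 0, -1, 0],
            [-1, 1, 1, 1, 1, 1],
        ],
        dtype=np.int8,
    )
    return AncestryMatrix(
        individuals=["i1", "i2", "i3", "i4"], markers=mm, calls=calls
    )
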