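import numpy as np
import pytest

from voxeldegree import CorrelationMatrix, ClusterMap, MaskGeometry


def line_geometry(V: int) -> MaskGeometry:
    """V voxels in a row: every pair of consecutive voxels is adjacent."""
    return MaskGeometry.from_mask(np.ones((V, 1, 1), dtype=bool))


def random_correlation_matrix(
    V: int, rng: np.random.Generator, lo: float = -0.8, hi: float = 0.9
) -> CorrelationMatrix:
    """Random symmetric matrix with unit diagonal and entries in [lo, hi]."""
    vals = rng.uniform(lo, hi, size=(V, V))
    vals = (vals + vals.T) / 2
    np.fill_diagonal(vals, 1.0)
    return CorrelationMatrix(
        values=vals,
        flavor="temporal",
        geometry=line_geometry(V),
        degenerate=np.zeros(V, dtype=bool),
    )


def random_cluster_map(
    V: int, rng: np.random.Generator, p: float = 0.3
) -> ClusterMap:
    """Random membership sets, each containing its seed."""
    clusters = []
    for i in range(V):
        members = np.flatnonzero(rng.random(V) < p)
        clusters.append(np.union1d(members, [i]))
    return ClusterMap(
        clusters=tuple(clusters),
        flavor="combined",
        T_a_used=0.5,
        geometry=line_geometry(V),
    )


def singleton_cluster_map(V: int) -> ClusterMap:
    return ClusterMap(
        clusters=tuple(np.array([i]) for i in range(V)),
        flavor="combined",
        T_a_used=0.5,
        geometry=line_geometry(V),
    )


@pytest.fixture
def rng():
    return np.random.default_rng(2024)


@pytest.fixture(scope="session")
def block_phantom():
    from voxeldegree import make_block_phantom

    return make_block_phantom(seed=0)


@pytest.fixture(scope="session")
def fitted_phantom(block_phantom):
    from voxeldegree import VoxelDegreeModel

    return VoxelDegreeModel(
        block_phantom.series, t_d_grid=(0.15, 0.3), metrics=("U", "W")
    ).fit()
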