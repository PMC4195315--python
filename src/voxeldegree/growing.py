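"""Seed-based region growing on a correlation matrix.

For every seed voxel i, the cluster C_i accretes 26-connected neighbours j
of the current cluster whose correlation with the *seed* satisfies
r(i, j) >= T_a, until no voxel can be added.  Because the criterion depends
only on the seed, the fixed point is independent of visit order: C_i is the
26-connected component containing i of the voxel set
{j : r(i, j) >= T_a} ∪ {i}.

Clusters from different seeds may overlap and need not agree; that
inconsistency is exactly what the region-growing error rate measures.
Temporal and spatial cluster maps are intersected per seed to form the
combined map used for degree correction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .connectivity import CorrelationMatrix
from .io import MaskGeometry

__all__ = ["ClusterMap", "grow_region", "grow_all", "combine_cluster_maps"]


@dataclass(frozen=True)
class ClusterMap:
    """Per-seed region-growing clusters.

    ``clusters[i]`` is the sorted array of in-mask voxel indices of C_i;
    the seed i is always a member.
    """

    clusters: tuple[np.ndarray, ...]
    flavor: Literal["temporal", "spatial", "combined"]
    T_a_used: float
    geometry: MaskGeometry

    def __post_init__(self) -> None:
        if len(self.clusters) != self.geometry.V:
            raise ValueError("one cluster per in-mask voxel required")
        for i, c in enumerate(self.clusters):
            if i not in c:
                raise ValueError(f"seed {i} missing from its own cluster")

    @property
    def V(self) -> int:
        return len(self.clusters)

    def sizes(self) -> np.ndarray:
        """Cluster size |C_i| per seed (the type I cluster-size values)."""
        return np.array([c.size for c in self.clusters], dtype=np.int64)

    def membership_matrix(self) -> np.ndarray:
        """Boolean (V, V) matrix B with B[i, j] = (j in C_i)."""
        B = np.zeros((self.V, self.V), dtype=bool)
        for i, c in enumerate(self.clusters):
            B[i, c] = True
        return B


def _adjacency_lists(geometry: MaskGeometry) -> list[np.ndarray]:
    return [geometry.neighbors26(v) for v in range(geometry.V)]


def grow_region(
    matrix: CorrelationMatrix,
    seed: int,
    T_a: float,
    geometry: MaskGeometry | None = None,
    _adj: Sequence[np.ndarray] | None = None,
) -> np.ndarray:
    """Grow the cluster of ``seed``; returns sorted voxel indices."""
    geometry = geometry if geometry is not None else matrix.geometry
    if not 0.0 < T_a < 1.0:
        raise ValueError("T_a must lie in (0, 1)")
    adj = _adj if _adj is not None else _adjacency_lists(geometry)
    eligible = matrix.values[seed] >= T_a
    eligible[seed] = True
    in_cluster = np.zeros(geometry.V, dtype=bool)
    in_cluster[seed] = True
    frontier = [seed]
    while frontier:
        nxt = []
        for v in frontier:
            for j in adj[v]:
                if eligible[j] and not in_cluster[j]:
                    in_cluster[j] = True
                    nxt.append(j)
        frontier = nxt
    return np.flatnonzero(in_cluster)


def grow_all(
    matrix: CorrelationMatrix, T_a: float, geometry: MaskGeometry | None = None
) -> ClusterMap:
    """Region growing from every voxel as seed."""
    geometry = geometry if geometry is not None else matrix.geometry
    adj = _adjacency_lists(geometry)
    clusters = tuple(
        grow_region(matrix, seed, T_a, geometry, _adj=adj)
        for seed in range(geometry.V)
    )
    return ClusterMap(
        clusters=clusters, flavor=matrix.flavor, T_a_used=T_a, geometry=geometry
    )


def combine_cluster_maps(temporal: ClusterMap, spatial: ClusterMap) -> ClusterMap:
    """Intersect temporal and spatial clusters per seed.

    The intersection may be disconnected; it is kept as-is, since degree
    correction only uses membership.
    """
    if temporal.geometry is not spatial.geometry and (
        temporal.geometry.shape != spatial.geometry.shape
        or temporal.V != spatial.V
        or not np.array_equal(temporal.geometry.coords, spatial.geometry.coords)
    ):
        raise ValueError("cluster maps have different geometries")
    if {temporal.flavor, spatial.flavor} != {"temporal", "spatial"}:
        raise ValueError("expected one temporal and one spatial cluster map")
    clusters = tuple(
        np.intersect1d(ct, cs, assume_unique=True)
        for ct, cs in zip(temporal.clusters, spatial.clusters)
    )
    return ClusterMap(
        clusters=clusters,
        flavor="combined",
        T_a_used=float("nan"),
        geometry=temporal.geometry,
    )
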