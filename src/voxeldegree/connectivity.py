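"""Temporal and spatial Pearson correlation matrices over in-mask voxels.

The *temporal* correlation of two voxels is the Pearson correlation of their
time series — the standard functional-connectivity edge weight.  The
*spatial* correlation of two voxels is the Pearson correlation of their
whole-brain temporal-correlation maps (their connectivity fingerprints),
excluding the two self positions from both maps so that the diagonal ones
and the mutual entry cannot leak trivial agreement.

Both computations are evaluated in row blocks so peak working memory beyond
the V x V result is bounded by ``block_size`` rows at a time.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal

import numpy as np

from .io import BoldSeries, MaskGeometry

__all__ = [
    "CorrelationMatrix",
    "temporal_correlation_matrix",
    "spatial_correlation_matrix",
    "mean_positive_correlation",
]

Flavor = Literal["temporal", "spatial"]

# variance below this (on standardized scales) counts as degenerate
_VAR_TOL = 1e-12


@dataclass(frozen=True)
class CorrelationMatrix:
    """Symmetric V x V matrix of Pearson coefficients.

    ``degenerate`` flags voxels whose input had zero variance; all their
    correlations (including the diagonal) are defined as 0 so they can never
    pass a positive threshold and never produce NaNs downstream.
    """

    values: np.ndarray
    flavor: Flavor
    geometry: MaskGeometry
    degenerate: np.ndarray

    def __post_init__(self) -> None:
        v = np.asarray(self.values)
        if v.ndim != 2 or v.shape[0] != v.shape[1]:
            raise ValueError("values must be a square matrix")
        if v.shape[0] != self.geometry.V:
            raise ValueError("matrix size does not match geometry")

    @property
    def V(self) -> int:
        return self.values.shape[0]


def _standardized_rows(data: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Center rows and scale to unit norm; zero-variance rows become 0."""
    centered = data - data.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(centered, axis=1)
    degenerate = norms <= _VAR_TOL * max(1.0, float(np.abs(data).max()))
    safe = np.where(degenerate, 1.0, norms)
    z = centered / safe[:, None]
    z[degenerate] = 0.0
    return z, degenerate


def temporal_correlation_matrix(
    series: BoldSeries, block_size: int | None = None
) -> CorrelationMatrix:
    """Pairwise Pearson correlations of the voxel time series.

    Parameters
    ----------
    series : BoldSeries
        Masked series with at least 3 time points.
    block_size : int, optional
        Number of rows per block in the blocked matrix product.  The result
        is identical (to floating-point noise) for any block size.
    """
    if series.T < 3:
        raise ValueError(f"need at least 3 time points, got {series.T}")
    z, degenerate = _standardized_rows(series.data)
    V = z.shape[0]
    values = np.empty((V, V), dtype=np.float64)
    step = V if not block_size else max(1, int(block_size))
    for start in range(0, V, step):
        stop = min(start + step, V)
        values[start:stop] = z[start:stop] @ z.T
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(values, np.where(degenerate, 0.0, 1.0))
    values[degenerate, :] = 0.0
    values[:, degenerate] = 0.0
    return CorrelationMatrix(
        values=values,
        flavor="temporal",
        geometry=series.geometry,
        degenerate=degenerate,
    )


def spatial_correlation_matrix(
    temporal: CorrelationMatrix, block_size: int | None = None
) -> CorrelationMatrix:
    """Correlate whole-brain connectivity fingerprints of voxel pairs.

    For a pair (i, j) the fingerprints are rows i and j of the temporal
    matrix with positions i and j removed from both, so the trivial diagonal
    agreement and the shared r(i, j) entry do not contribute.  Pairs whose
    reduced fingerprints have zero variance get correlation 0.
    """
    if temporal.flavor != "temporal":
        raise ValueError("input must be a temporal correlation matrix")
    V = temporal.V
    if V < 4:
        raise ValueError("need at least 4 voxels for spatial correlation")
    R = temporal.values
    d = np.diag(R).copy()
    s = R.sum(axis=1)
    q = (R * R).sum(axis=1)
    m = V - 2  # length of each reduced fingerprint

    values = np.empty((V, V), dtype=np.float64)
    step = V if not block_size else max(1, int(block_size))
    for start in range(0, V, step):
        stop = min(start + step, V)
        Rb = R[start:stop]  # (b, V)
        G = Rb @ R.T
        # moments of row i (block) and row j with positions i and j removed
        sum_a = s[start:stop, None] - d[start:stop, None] - Rb
        sum_b = s[None, :] - d[None, :] - Rb
        ss_a = q[start:stop, None] - d[start:stop, None] ** 2 - Rb**2
        ss_b = q[None, :] - d[None, :] ** 2 - Rb**2
        cross = G - d[start:stop, None] * Rb - Rb * d[None, :]
        cov = cross - sum_a * sum_b / m
        var_a = ss_a - sum_a**2 / m
        var_b = ss_b - sum_b**2 / m
        ok = (var_a > _VAR_TOL) & (var_b > _VAR_TOL)
        denom = np.sqrt(np.where(ok, var_a * var_b, 1.0))
        values[start:stop] = np.where(ok, cov / denom, 0.0)
    values = np.clip((values + values.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(values, np.where(temporal.degenerate, 0.0, 1.0))
    values[temporal.degenerate, :] = 0.0
    values[:, temporal.degenerate] = 0.0
    return CorrelationMatrix(
        values=values,
        flavor="spatial",
        geometry=temporal.geometry,
        degenerate=temporal.degenerate.copy(),
    )


def mean_positive_correlation(matrix: CorrelationMatrix) -> float:
    """Mean of the strictly positive off-diagonal correlations.

    Each unordered voxel pair is counted once (upper triangle); the diagonal
    is excluded so its ones do not bias the mean upward.
    """
    iu = np.triu_indices(matrix.V, k=1)
    vals = matrix.values[iu]
    pos = vals[vals > 0]
    if pos.size == 0:
        raise ValueError("matrix has no positive off-diagonal correlations")
    return float(pos.mean())
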