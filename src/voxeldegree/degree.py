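"""Traditional and region-size-corrected degree metrics.

Four weight schemes are supported, each summed over the voxel pairs whose
correlation passes a connectivity threshold T_d:

* ``U``  — unweighted degree, weight 1 per connection;
* ``W``  — weighted degree, weight r;
* ``WS`` — intrinsic connectivity contrast, weight r^2;
* ``WF`` — Fisher-z weighted degree, weight atanh(r) = ln((1+r)/(1-r))/2.

The corrected (RSE, "reduce size effect") variants additionally take a
per-seed cluster map estimating each voxel's functional region:

    D_RSE(i) = sum_j w(i,j) * f(i,j) * g(i,j) / s(i,j)

with f(i,j) = [r(i,j) >= T_d] the connection indicator, g(i,j) = 0 when j
lies in i's own cluster C_i (drops within-region self-connections) and
s(i,j) = |{k in C_j \\ C_i : r(i,k) >= T_d}| (divides each cross-region
connection by the effective size of the connected region).  Whenever a term
survives (f=1, g=1), j itself belongs to C_j \\ C_i and is connected to i,
so s >= 1 and the division is always defined.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np

from .connectivity import CorrelationMatrix
from .growing import ClusterMap

__all__ = [
    "Metric",
    "DegreeConfig",
    "DegreeResult",
    "DEFAULT_T_D_GRID",
    "METRICS",
    "indicator",
    "weight",
    "traditional_degree",
    "rse_degree",
    "threshold_sweep",
]

Metric = Literal["U", "W", "WS", "WF"]
METRICS: tuple[Metric, ...] = ("U", "W", "WS", "WF")

#: connectivity thresholds 0.15 to 0.5 in steps of 0.05
DEFAULT_T_D_GRID: tuple[float, ...] = tuple(
    np.round(np.arange(0.15, 0.5001, 0.05), 2)
)


@dataclass(frozen=True)
class DegreeConfig:
    """Which degree metric to compute, at which connectivity threshold.

    ``include_self`` enables the literal reading of the degree sums in which
    the j = i term (r = 1) is not excluded; the default drops it, since a
    constant offset carries no hub information and the corrected metrics
    drop it anyway through g.
    """

    T_d: float
    metric: Metric = "U"
    corrected: bool = False
    include_self: bool = False

    def __post_init__(self) -> None:
        if not 0.0 < self.T_d < 1.0:
            raise ValueError("T_d must lie in (0, 1)")
        if self.metric not in METRICS:
            raise ValueError(f"unknown metric {self.metric!r}")


@dataclass(frozen=True)
class DegreeResult:
    """Per-voxel values of one degree metric at one threshold."""

    values: np.ndarray
    config: DegreeConfig
    cluster_map_id: str | None = None

    def __post_init__(self) -> None:
        if self.config.corrected and self.cluster_map_id is None:
            raise ValueError("corrected result requires cluster provenance")


def indicator(r: float, T_d: float) -> int:
    """Connection indicator f: 1 iff r >= T_d (inclusive)."""
    return int(r >= T_d)


def weight(r, metric: Metric):
    """Connection weight w(r) for one metric; scalar or elementwise.

    WF rejects |r| = 1 (duplicated time series give an infinite Fisher-z
    weight) rather than clamping.
    """
    r = np.asarray(r, dtype=np.float64)
    if metric == "U":
        out = np.ones_like(r)
    elif metric == "W":
        out = r.copy()
    elif metric == "WS":
        out = r * r
    elif metric == "WF":
        if np.any(np.abs(r) >= 1.0):
            raise ValueError("|r| = 1 has infinite Fisher-z weight")
        out = np.arctanh(r)
    else:
        raise ValueError(f"unknown metric {metric!r}")
    return out if out.ndim else float(out)


def _weight_matrix(R: np.ndarray, metric: Metric, used: np.ndarray) -> np.ndarray:
    """Weights for the entries flagged in ``used``; zeros elsewhere."""
    if metric == "U":
        return used.astype(np.float64)
    if metric == "W":
        return np.where(used, R, 0.0)
    if metric == "WS":
        return np.where(used, R * R, 0.0)
    if metric == "WF":
        if np.any(np.abs(R[used]) >= 1.0):
            raise ValueError(
                "correlation with |r| = 1 passed the connectivity threshold; "
                "Fisher-z weight is infinite"
            )
        return np.where(used, np.arctanh(np.where(used, R, 0.0)), 0.0)
    raise ValueError(f"unknown metric {metric!r}")


def _connection_mask(R: np.ndarray, config: DegreeConfig) -> np.ndarray:
    A = R >= config.T_d
    if not config.include_self:
        np.fill_diagonal(A, False)
    return A


def traditional_degree(
    matrix: CorrelationMatrix, config: DegreeConfig
) -> DegreeResult:
    """Uncorrected degree: sum of weights over suprathreshold connections."""
    if config.corrected:
        raise ValueError("use rse_degree for corrected metrics")
    A = _connection_mask(matrix.values, config)
    W = _weight_matrix(matrix.values, config.metric, A)
    return DegreeResult(values=W.sum(axis=1), config=config)


def rse_degree(
    matrix: CorrelationMatrix, config: DegreeConfig, clusters: ClusterMap
) -> DegreeResult:
    """Region-size-corrected degree (see module docstring for the formula)."""
    if not config.corrected:
        raise ValueError("config.corrected must be True for rse_degree")
    if clusters.V != matrix.V:
        raise ValueError("cluster map does not match matrix size")
    R = matrix.values
    V = matrix.V
    A = R >= config.T_d
    np.fill_diagonal(A, False)  # g drops j = i regardless (i is in C_i)
    W = _weight_matrix(R, config.metric, A)
    B = clusters.membership_matrix()
    values = np.zeros(V, dtype=np.float64)
    a_int = A.astype(np.int64)
    for i in range(V):
        surviving = A[i] & ~B[i]  # f(i,j) = 1 and g(i,j) = 1
        j_idx = np.flatnonzero(surviving)
        if j_idx.size == 0:
            continue
        # s(i,j) = |{k in C_j \ C_i : r(i,k) >= T_d}| for each surviving j
        s = (B[j_idx] & ~B[i]) @ a_int[i]
        assert np.all(s >= 1), "s(i,j) must be >= 1 when f*g = 1"
        values[i] = (W[i, j_idx] / s).sum()
    return DegreeResult(
        values=values,
        config=config,
        cluster_map_id=f"{clusters.flavor}:T_a={clusters.T_a_used}",
    )


def threshold_sweep(
    matrix: CorrelationMatrix,
    clusters: ClusterMap,
    grid: Sequence[float] = DEFAULT_T_D_GRID,
    metrics: Sequence[Metric] = METRICS,
) -> list[DegreeResult]:
    """All traditional and corrected metrics at each threshold in ``grid``."""
    if len(grid) == 0:
        raise ValueError("threshold grid is empty")
    results: list[DegreeResult] = []
    for t_d in grid:
        for metric in metrics:
            results.append(
                traditional_degree(
                    matrix, DegreeConfig(T_d=float(t_d), metric=metric)
                )
            )
            results.append(
                rse_degree(
                    matrix,
                    DegreeConfig(T_d=float(t_d), metric=metric, corrected=True),
                    clusters,
                )
            )
    return results
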