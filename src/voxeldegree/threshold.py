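"""Data-driven estimation of the region-growing threshold T_a.

The estimate assumes that a voxel's face neighbours are the voxels most
likely to share its functional region, so their correlations with the voxel
bound the within-region correlation level.  A two-step filter keeps only the
high end of each voxel's neighbour correlations:

1. drop neighbours whose correlation is negative or below the mean positive
   correlation of the whole matrix (removes noise and boundary neighbours);
2. drop neighbours strictly below the mean of the step-1 survivors.

The voxel's threshold is the mean correlation of the final survivors, and
T_a is the average of the per-voxel thresholds over all voxels that have one.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from typing import Literal

import numpy as np

from .connectivity import CorrelationMatrix, mean_positive_correlation
from .io import MaskGeometry

__all__ = ["ThresholdReport", "voxel_threshold", "adaptive_threshold"]


@dataclass(frozen=True)
class ThresholdReport:
    """Result of the adaptive-threshold estimation for one matrix."""

    T_a: float
    per_voxel_thresholds: np.ndarray  # NaN where undefined
    n_excluded_voxels: int
    flavor: Literal["temporal", "spatial"]
    mean_positive: float

    def to_json(self) -> str:
        return json.dumps(
            {
                "T_a": self.T_a,
                "flavor": self.flavor,
                "n_excluded_voxels": self.n_excluded_voxels,
                "n_defined_voxels": int(
                    np.isfinite(self.per_voxel_thresholds).sum()
                ),
                "mean_positive_correlation": self.mean_positive,
            }
        )


def voxel_threshold(
    matrix: CorrelationMatrix,
    voxel: int,
    geometry: MaskGeometry | None = None,
    mean_pos: float | None = None,
) -> float:
    """Two-step filtered mean of a voxel's face-neighbour correlations.

    Returns NaN when no neighbour survives the first filter (isolated or
    anti-correlated voxels); such voxels do not enter the T_a average.
    Voxels at the mask edge use whatever face neighbours lie in the mask.
    """
    geometry = geometry if geometry is not None else matrix.geometry
    if mean_pos is None:
        mean_pos = mean_positive_correlation(matrix)
    nb = geometry.neighbors6(voxel)
    if nb.size == 0:
        return float("nan")
    r = matrix.values[voxel, nb]
    # step 1: drop negatives and correlations below the matrix-wide mean
    # positive level
    survivors = r[r >= mean_pos]
    if survivors.size == 0:
        return float("nan")
    # step 2: drop survivors strictly below their own mean; ties survive
    level = survivors.mean()
    final = survivors[survivors >= level]
    if final.size == 0:
        # near-equal survivors whose float mean rounded above the maximum
        return float(level)
    return float(final.mean())


def adaptive_threshold(
    matrix: CorrelationMatrix, geometry: MaskGeometry | None = None
) -> ThresholdReport:
    """Estimate T_a by averaging per-voxel thresholds over the mask."""
    geometry = geometry if geometry is not None else matrix.geometry
    mean_pos = mean_positive_correlation(matrix)
    per_voxel = np.array(
        [
            voxel_threshold(matrix, v, geometry, mean_pos)
            for v in range(geometry.V)
        ]
    )
    defined = np.isfinite(per_voxel)
    if not defined.any():
        raise ValueError("no voxel has a defined threshold; cannot estimate T_a")
    return ThresholdReport(
        T_a=float(per_voxel[defined].mean()),
        per_voxel_thresholds=per_voxel,
        n_excluded_voxels=int((~defined).sum()),
        flavor=matrix.flavor,
        mean_positive=mean_pos,
    )
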