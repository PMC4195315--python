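"""Region-growing quality indices and map post-processing.

Two indirect quality measures for seed-based region growing:

* the region-growing error rate (RGER): the fraction of unordered voxel
  pairs {i, j} with asymmetric membership (j in C_i but i not in C_j, or
  vice versa) — a global index;
* agreement between the two cluster-size maps: the type I map M_i = |C_i|
  (how many voxels i's cluster contains) and the type II map
  N_i = #{j : i in C_j} (how many clusters contain i).  Perfectly symmetric
  growing makes the two maps identical, so their across-subject intra-class
  correlation is a voxel-wise (local) quality index.

Also provides the z-scoring, mask-aware Gaussian smoothing, and the ICC
computation shared with the test–retest reliability analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .growing import ClusterMap
from .io import MaskGeometry

__all__ = [
    "ClusterSizeMaps",
    "rger",
    "cluster_size_maps",
    "zscore_map",
    "smooth_map",
    "icc",
    "map_agreement_icc",
]

_FWHM_TO_SIGMA = 1.0 / (2.0 * np.sqrt(2.0 * np.log(2.0)))


@dataclass(frozen=True)
class ClusterSizeMaps:
    """Type I (own-cluster size M) and type II (containing-cluster count N)."""

    type_I: np.ndarray
    type_II: np.ndarray


def rger(cluster_map: ClusterMap) -> float:
    """Region-growing error rate over unordered voxel pairs.

    A pair {i, j} is an error when exactly one of (j in C_i), (i in C_j)
    holds; the rate divides by V(V-1)/2.  Zero means perfectly symmetric
    growing.
    """
    V = cluster_map.V
    if V < 2:
        raise ValueError("need at least 2 voxels")
    B = cluster_map.membership_matrix()
    asym = B != B.T
    errors = int(np.triu(asym, k=1).sum())
    return errors / (V * (V - 1) / 2)


def cluster_size_maps(cluster_map: ClusterMap) -> ClusterSizeMaps:
    """Per-voxel M_i = |C_i| and N_i = number of clusters containing i.

    N counts *all* clusters containing i, C_i included, so that perfectly
    symmetric growing gives M = N exactly.
    """
    B = cluster_map.membership_matrix()
    return ClusterSizeMaps(
        type_I=B.sum(axis=1).astype(np.int64),
        type_II=B.sum(axis=0).astype(np.int64),
    )


def zscore_map(values: np.ndarray, ddof: int = 0) -> np.ndarray:
    """Standardize in-mask values to mean 0, SD 1 (population SD by default)."""
    values = np.asarray(values, dtype=np.float64)
    sd = values.std(ddof=ddof)
    if sd == 0:
        raise ValueError("cannot z-score a constant map")
    return (values - values.mean()) / sd


def smooth_map(
    values: np.ndarray,
    geometry: MaskGeometry,
    fwhm_mm: float = 8.0,
    truncate: float = 4.0,
) -> np.ndarray:
    """Mask-normalized 3-D Gaussian smoothing of a per-voxel map.

    The kernel sigma per axis is ``fwhm / (2 sqrt(2 ln 2))`` converted to
    voxel units with the geometry's voxel size.  Out-of-mask voxels are
    excluded by dividing the smoothed zero-filled volume by the smoothed
    mask, which preserves constant maps exactly and keeps positivity.
    ``fwhm_mm = 0`` is the identity.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (geometry.V,):
        raise ValueError(f"expected {geometry.V} values")
    if fwhm_mm < 0:
        raise ValueError("fwhm_mm must be non-negative")
    if fwhm_mm == 0:
        return values.copy()
    sigma = [
        fwhm_mm * _FWHM_TO_SIGMA / vs for vs in geometry.voxel_size
    ]
    vol = geometry.unmask(values, background=0.0)
    mask = geometry.unmask(np.ones(geometry.V), background=0.0)
    num = ndimage.gaussian_filter(
        vol, sigma=sigma, truncate=truncate, mode="constant", cval=0.0
    )
    den = ndimage.gaussian_filter(
        mask, sigma=sigma, truncate=truncate, mode="constant", cval=0.0
    )
    smoothed = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return smoothed[tuple(geometry.coords.T)]


def icc(measurements: np.ndarray, variant: str = "a1") -> np.ndarray:
    """Intra-class correlation, vectorized over trailing axes.

    Parameters
    ----------
    measurements : ndarray, shape (n_subjects, k_raters, ...)
        Two-way table(s); the ICC is computed independently for each
        trailing position (e.g. voxel).
    variant : {"a1", "c1"}
        ``a1``: two-way model, absolute agreement, single measurement
        (ICC(A,1) of McGraw & Wong — numerically identical to ICC(2,1)).
        ``c1``: two-way model, consistency, single measurement (ICC(C,1) /
        ICC(3,1)).

    Returns NaN where the table is totally degenerate (no variance at all).
    """
    Y = np.asarray(measurements, dtype=np.float64)
    if Y.ndim < 2:
        raise ValueError("measurements must have shape (n, k, ...)")
    n, k = Y.shape[0], Y.shape[1]
    if n < 3:
        raise ValueError("need at least 3 subjects")
    if k < 2:
        raise ValueError("need at least 2 raters")
    grand = Y.mean(axis=(0, 1))
    row_means = Y.mean(axis=1)  # (n, ...)
    col_means = Y.mean(axis=0)  # (k, ...)
    ssr = k * ((row_means - grand) ** 2).sum(axis=0)
    ssc = n * ((col_means - grand) ** 2).sum(axis=0)
    sst = ((Y - grand) ** 2).sum(axis=(0, 1))
    sse = sst - ssr - ssc
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    if variant == "a1":
        denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
    elif variant == "c1":
        denom = msr + (k - 1) * mse
    else:
        raise ValueError(f"unknown ICC variant {variant!r}")
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(np.abs(denom) > 0, (msr - mse) / denom, np.nan)
    return out


def map_agreement_icc(
    maps_a: np.ndarray, maps_b: np.ndarray, variant: str = "a1"
) -> np.ndarray:
    """Voxel-wise ICC across subjects between two map types.

    ``maps_a`` and ``maps_b`` are (n_subjects, V) arrays (typically z-scored
    and smoothed type I and type II cluster-size maps); the two types act as
    the two measurements at each voxel.
    """
    a = np.asarray(maps_a, dtype=np.float64)
    b = np.asarray(maps_b, dtype=np.float64)
    if a.shape != b.shape or a.ndim != 2:
        raise ValueError("maps_a and maps_b must be matching (n_subjects, V)")
    if a.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    return icc(np.stack([a, b], axis=1), variant=variant)
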