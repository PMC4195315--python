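"""Test–retest reliability of degree maps.

Reliability is measured voxel-wise across subjects as the intra-class
correlation between the map from a first scan and the average of the maps
from two later scans (averaging the retest scans improves the long-term
reliability estimate).  Maps are z-scored and then smoothed before the ICC,
mirroring the preparation used for group analyses.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from .degree import DegreeResult, Metric
from .evaluation import icc, smooth_map, zscore_map
from .io import MaskGeometry

__all__ = ["ReliabilityResult", "test_retest_icc", "reliability_sweep", "prepare_map"]


@dataclass(frozen=True)
class ReliabilityResult:
    """Voxel-wise test–retest ICC map for one degree configuration."""

    icc_map: np.ndarray
    n_subjects: int
    metric: Metric | None = None
    corrected: bool | None = None
    T_d: float | None = None

    @property
    def mean_icc(self) -> float:
        """Mask-mean ICC over voxels where it is defined."""
        finite = np.isfinite(self.icc_map)
        if not finite.any():
            return float("nan")
        return float(self.icc_map[finite].mean())


def prepare_map(
    values: np.ndarray, geometry: MaskGeometry | None, fwhm_mm: float = 8.0
) -> np.ndarray:
    """Z-score then smooth one subject map (constant maps pass through as 0)."""
    values = np.asarray(values, dtype=np.float64)
    if values.std() == 0:
        z = np.zeros_like(values)
    else:
        z = zscore_map(values)
    if geometry is None or fwhm_mm == 0:
        return z
    return smooth_map(z, geometry, fwhm_mm=fwhm_mm)


def test_retest_icc(
    scan1_maps: np.ndarray,
    scan2_maps: np.ndarray,
    scan3_maps: np.ndarray,
    variant: str = "a1",
    metric: Metric | None = None,
    corrected: bool | None = None,
    T_d: float | None = None,
) -> ReliabilityResult:
    """Voxel-wise ICC between scan 1 and the mean of scans 2 and 3.

    Each ``scanX_maps`` is an (n_subjects, V) array of already prepared
    (z-scored, smoothed) maps.  Voxels with zero across-subject variance in
    either measurement are reported as NaN and excluded from summary means.
    """
    s1 = np.asarray(scan1_maps, dtype=np.float64)
    s2 = np.asarray(scan2_maps, dtype=np.float64)
    s3 = np.asarray(scan3_maps, dtype=np.float64)
    if not (s1.shape == s2.shape == s3.shape) or s1.ndim != 2:
        raise ValueError("all scans need matching (n_subjects, V) maps")
    if s1.shape[0] < 3:
        raise ValueError("need at least 3 subjects")
    retest = (s2 + s3) / 2.0
    values = icc(np.stack([s1, retest], axis=1), variant=variant)
    dead = (s1.std(axis=0) == 0) | (retest.std(axis=0) == 0)
    values = np.where(dead, np.nan, values)
    return ReliabilityResult(
        icc_map=values,
        n_subjects=s1.shape[0],
        metric=metric,
        corrected=corrected,
        T_d=T_d,
    )


def _group_results(
    subject_results: Sequence[Sequence[DegreeResult]],
) -> dict[tuple[Metric, bool, float], np.ndarray]:
    """Stack per-subject DegreeResult lists into (metric, corrected, T_d) -> (n, V)."""
    grouped: dict[tuple[Metric, bool, float], list[np.ndarray]] = {}
    for results in subject_results:
        for res in results:
            key = (res.config.metric, res.config.corrected, res.config.T_d)
            grouped.setdefault(key, []).append(res.values)
    return {k: np.vstack(v) for k, v in grouped.items()}


def reliability_sweep(
    scan1: Sequence[Sequence[DegreeResult]],
    scan2: Sequence[Sequence[DegreeResult]],
    scan3: Sequence[Sequence[DegreeResult]],
    geometry: MaskGeometry | None = None,
    fwhm_mm: float = 8.0,
    variant: str = "a1",
) -> pd.DataFrame:
    """Tabulate mean test–retest ICC per (metric, corrected, T_d).

    Each ``scanX`` is a per-subject sequence of raw ``DegreeResult`` lists
    (e.g. from ``threshold_sweep``); maps are z-scored and smoothed here.
    Returns a DataFrame with one row per configuration and a boolean
    ``optimal`` column marking, per (metric, corrected), the threshold with
    the highest mean ICC.
    """
    tables = [_group_results(scan) for scan in (scan1, scan2, scan3)]
    keys = sorted(tables[0], key=lambda k: (k[0], k[1], k[2]))
    if any(set(t) != set(keys) for t in tables):
        raise ValueError("scans contain different degree configurations")
    rows = []
    for metric, corrected, t_d in keys:
        prepared = [
            np.vstack(
                [prepare_map(m, geometry, fwhm_mm) for m in t[(metric, corrected, t_d)]]
            )
            for t in tables
        ]
        result = test_retest_icc(
            *prepared, variant=variant, metric=metric, corrected=corrected, T_d=t_d
        )
        rows.append(
            {
                "metric": metric,
                "corrected": corrected,
                "T_d": t_d,
                "mean_icc": result.mean_icc,
                "n_subjects": result.n_subjects,
            }
        )
    table = pd.DataFrame(rows)
    table["optimal"] = False
    for _, grp in table.groupby(["metric", "corrected"]):
        if grp["mean_icc"].notna().any():
            table.loc[grp["mean_icc"].idxmax(), "optimal"] = True
    return table
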