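"""Model/Results facade over the degree-correction pipeline.

``VoxelDegreeModel`` is built from a masked BOLD series (or NIfTI paths)
and configuration; ``fit()`` runs the six analysis stages — temporal
correlation, spatial correlation, adaptive thresholds, region growing per
flavor, combination, degree metrics — and returns a ``VoxelDegreeResults``
holding the thresholds, cluster maps, quality indices and all degree maps,
with a ``summary()`` table.
"""

from __future__ import annotations

import json
import time
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from . import evaluation
from .connectivity import (
    CorrelationMatrix,
    spatial_correlation_matrix,
    temporal_correlation_matrix,
)
from .degree import DEFAULT_T_D_GRID, METRICS, DegreeResult, Metric, threshold_sweep
from .growing import ClusterMap, combine_cluster_maps, grow_all
from .io import BoldSeries, load_bold, write_map
from .threshold import ThresholdReport, adaptive_threshold

__all__ = ["VoxelDegreeModel", "VoxelDegreeResults"]


class VoxelDegreeModel:
    """Region-size-corrected degree analysis of one subject's BOLD series.

    Parameters
    ----------
    series : BoldSeries
        Masked voxel time series.
    t_d_grid : sequence of float
        Connectivity thresholds to sweep (default 0.15 to 0.5, step 0.05).
    metrics : sequence of {"U", "W", "WS", "WF"}
        Degree weight schemes to compute.
    block_size : int, optional
        Row-block size for the correlation computations.
    """

    def __init__(
        self,
        series: BoldSeries,
        t_d_grid: Sequence[float] = DEFAULT_T_D_GRID,
        metrics: Sequence[Metric] = METRICS,
        block_size: int | None = None,
    ):
        self.series = series
        self.t_d_grid = tuple(float(t) for t in t_d_grid)
        self.metrics = tuple(metrics)
        self.block_size = block_size

    @classmethod
    def from_nifti(cls, bold_path, mask_path, **kwargs) -> "VoxelDegreeModel":
        return cls(load_bold(bold_path, mask_path), **kwargs)

    def fit(self) -> "VoxelDegreeResults":
        timings = {}
        t0 = time.perf_counter()
        temporal = temporal_correlation_matrix(self.series, self.block_size)
        timings["temporal_correlation"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        spatial = spatial_correlation_matrix(temporal, self.block_size)
        timings["spatial_correlation"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        report_t = adaptive_threshold(temporal)
        report_s = adaptive_threshold(spatial)
        timings["adaptive_threshold"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        grown_t = grow_all(temporal, report_t.T_a)
        grown_s = grow_all(spatial, report_s.T_a)
        timings["region_growing"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        combined = combine_cluster_maps(grown_t, grown_s)
        timings["combination"] = time.perf_counter() - t0

        t0 = time.perf_counter()
        degrees = threshold_sweep(temporal, combined, self.t_d_grid, self.metrics)
        timings["degree"] = time.perf_counter() - t0

        return VoxelDegreeResults(
            model=self,
            temporal_matrix=temporal,
            spatial_matrix=spatial,
            threshold_temporal=report_t,
            threshold_spatial=report_s,
            clusters_temporal=grown_t,
            clusters_spatial=grown_s,
            clusters_combined=combined,
            degree_results=tuple(degrees),
            timings=timings,
        )


@dataclass(frozen=True)
class VoxelDegreeResults:
    """Fitted pipeline state: thresholds, clusters, quality indices, degrees."""

    model: VoxelDegreeModel
    temporal_matrix: CorrelationMatrix
    spatial_matrix: CorrelationMatrix
    threshold_temporal: ThresholdReport
    threshold_spatial: ThresholdReport
    clusters_temporal: ClusterMap
    clusters_spatial: ClusterMap
    clusters_combined: ClusterMap
    degree_results: tuple[DegreeResult, ...]
    timings: dict = field(default_factory=dict)

    @property
    def rger(self) -> float:
        """Region-growing error rate of the combined cluster map."""
        return evaluation.rger(self.clusters_combined)

    @property
    def cluster_size_maps(self) -> evaluation.ClusterSizeMaps:
        return evaluation.cluster_size_maps(self.clusters_combined)

    def degree_map(
        self, metric: Metric, T_d: float, corrected: bool
    ) -> np.ndarray:
        for res in self.degree_results:
            c = res.config
            if (
                c.metric == metric
                and c.corrected == corrected
                and np.isclose(c.T_d, T_d)
            ):
                return res.values
        raise KeyError(f"no degree result for ({metric}, T_d={T_d}, {corrected})")

    def degree_table(self) -> pd.DataFrame:
        rows = []
        for res in self.degree_results:
            rows.append(
                {
                    "metric": res.config.metric,
                    "corrected": res.config.corrected,
                    "T_d": res.config.T_d,
                    "mean": float(res.values.mean()),
                    "sd": float(res.values.std()),
                    "max": float(res.values.max()),
                }
            )
        return pd.DataFrame(rows)

    def summary(self) -> str:
        sizes = self.cluster_size_maps
        lines = [
            "Region-size-corrected degree analysis",
            "=" * 53,
            f"Voxels: {self.temporal_matrix.V}"
            f"   time points: {self.model.series.T}",
            f"Adaptive threshold T_a (temporal): "
            f"{self.threshold_temporal.T_a:.4f}"
            f"  (excluded voxels: {self.threshold_temporal.n_excluded_voxels})",
            f"Adaptive threshold T_a (spatial):  "
            f"{self.threshold_spatial.T_a:.4f}"
            f"  (excluded voxels: {self.threshold_spatial.n_excluded_voxels})",
            f"Region-growing error rate (combined): {self.rger:.4%}",
            f"Cluster sizes (type I): mean {sizes.type_I.mean():.2f}, "
            f"max {sizes.type_I.max()}",
            "",
            self.degree_table().to_string(index=False),
        ]
        return "\n".join(lines)

    def save(self, outdir) -> dict:
        """Write threshold reports, quality maps and degree maps; return manifest."""
        import hashlib
        from pathlib import Path

        from .store import mask_hash, save_clusters, save_matrix

        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        geometry = self.temporal_matrix.geometry
        artifacts = {}

        def _register(path):
            h = hashlib.sha256(Path(path).read_bytes()).hexdigest()
            artifacts[Path(path).name] = h

        for name, report in (
            ("t_a_temporal.json", self.threshold_temporal),
            ("t_a_spatial.json", self.threshold_spatial),
        ):
            (outdir / name).write_text(report.to_json())
            _register(outdir / name)
        save_matrix(self.temporal_matrix, outdir / "temporal_corr.npz")
        _register(outdir / "temporal_corr.npz")
        save_clusters(self.clusters_combined, outdir / "clusters_combined.npz")
        _register(outdir / "clusters_combined.npz")
        sizes = self.cluster_size_maps
        write_map(sizes.type_I.astype(float), geometry, outdir / "type_I.nii")
        _register(outdir / "type_I.nii")
        write_map(sizes.type_II.astype(float), geometry, outdir / "type_II.nii")
        _register(outdir / "type_II.nii")
        (outdir / "rger.json").write_text(json.dumps({"rger": self.rger}))
        _register(outdir / "rger.json")
        for res in self.degree_results:
            c = res.config
            tag = f"{c.metric}{'_RSE' if c.corrected else ''}_Td{c.T_d:.2f}"
            write_map(res.values, geometry, outdir / f"degree_{tag}.nii")
            _register(outdir / f"degree_{tag}.nii")
        manifest = {
            "mask_hash": mask_hash(geometry),
            "t_d_grid": list(self.model.t_d_grid),
            "metrics": list(self.model.metrics),
            "timings_s": {k: round(v, 4) for k, v in self.timings.items()},
            "artifacts": artifacts,
        }
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        return manifest
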