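"""On-disk persistence of correlation matrices and cluster maps.

Both containers are NumPy ``.npz`` archives carrying the mask geometry
(grid shape, in-mask coordinates, voxel size, affine) and a hash of the
mask so that downstream stages can refuse mismatched inputs.  Cluster maps
are stored as a ragged concatenation with offsets.
"""

from __future__ import annotations

import hashlib

import numpy as np

from .connectivity import CorrelationMatrix
from .growing import ClusterMap
from .io import MaskGeometry

__all__ = [
    "mask_hash",
    "save_matrix",
    "load_matrix",
    "save_clusters",
    "load_clusters",
]


def mask_hash(geometry: MaskGeometry) -> str:
    h = hashlib.sha256()
    h.update(np.asarray(geometry.shape, dtype=np.int64).tobytes())
    h.update(geometry.coords.astype(np.int64).tobytes())
    return h.hexdigest()


def _geometry_payload(geometry: MaskGeometry) -> dict:
    return {
        "grid_shape": np.asarray(geometry.shape, dtype=np.int64),
        "coords": geometry.coords,
        "voxel_size": np.asarray(geometry.voxel_size, dtype=np.float64),
        "affine": geometry.affine,
        "mask_hash": np.array(mask_hash(geometry)),
    }


def _geometry_from(payload) -> MaskGeometry:
    return MaskGeometry(
        shape=tuple(int(x) for x in payload["grid_shape"]),
        coords=payload["coords"],
        voxel_size=tuple(float(x) for x in payload["voxel_size"]),
        affine=payload["affine"],
    )


def save_matrix(matrix: CorrelationMatrix, path) -> None:
    np.savez_compressed(
        path,
        values=matrix.values,
        flavor=np.array(matrix.flavor),
        degenerate=matrix.degenerate,
        **_geometry_payload(matrix.geometry),
    )


def load_matrix(path) -> CorrelationMatrix:
    with np.load(path, allow_pickle=False) as z:
        return CorrelationMatrix(
            values=z["values"],
            flavor=str(z["flavor"]),
            geometry=_geometry_from(z),
            degenerate=z["degenerate"],
        )


def save_clusters(cluster_map: ClusterMap, path) -> None:
    flat = np.concatenate(cluster_map.clusters)
    offsets = np.cumsum([0] + [c.size for c in cluster_map.clusters])
    np.savez_compressed(
        path,
        flat=flat,
        offsets=offsets,
        flavor=np.array(cluster_map.flavor),
        T_a_used=np.array(cluster_map.T_a_used),
        **_geometry_payload(cluster_map.geometry),
    )


def load_clusters(path) -> ClusterMap:
    with np.load(path, allow_pickle=False) as z:
        flat, offsets = z["flat"], z["offsets"]
        clusters = tuple(
            flat[offsets[i] : offsets[i + 1]] for i in range(offsets.size - 1)
        )
        return ClusterMap(
            clusters=clusters,
            flavor=str(z["flavor"]),
            T_a_used=float(z["T_a_used"]),
            geometry=_geometry_from(z),
        )
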