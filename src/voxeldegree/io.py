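"""NIfTI input/output and mask geometry.

All in-memory computation works on *masked* data: a ``BoldSeries`` holds a
``V x T`` matrix whose rows are the time series of in-mask voxels, ordered by
ascending C-order linear index of the 3-D grid.  ``MaskGeometry`` provides the
bijection between that linear ordering and grid coordinates, plus 6- and
26-neighbourhoods restricted to the mask.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import nibabel as nib
import numpy as np

__all__ = ["MaskGeometry", "BoldSeries", "load_bold", "write_map"]

# offsets of the 6 face neighbours and the 26 neighbours of a voxel
_OFF6 = np.array(
    [[-1, 0, 0], [1, 0, 0], [0, -1, 0], [0, 1, 0], [0, 0, -1], [0, 0, 1]],
    dtype=np.int64,
)
_OFF26 = np.array(
    [
        [dx, dy, dz]
        for dx in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dz in (-1, 0, 1)
        if (dx, dy, dz) != (0, 0, 0)
    ],
    dtype=np.int64,
)


@dataclass(frozen=True)
class MaskGeometry:
    """Geometry of a binary voxel mask on a regular 3-D grid.

    Parameters
    ----------
    shape : tuple of int
        Grid dimensions ``(nx, ny, nz)``.
    coords : ndarray, shape (V, 3)
        Grid coordinates of the in-mask voxels, in ascending C-order linear
        index (the canonical voxel ordering used everywhere in this package).
    voxel_size : tuple of float
        Physical voxel edge lengths in millimetres.
    affine : ndarray, shape (4, 4)
        Voxel-to-world affine, used only when writing NIfTI output.
    """

    shape: tuple[int, int, int]
    coords: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray = field(default_factory=lambda: np.eye(4))

    def __post_init__(self) -> None:
        coords = np.asarray(self.coords, dtype=np.int64)
        if coords.ndim != 2 or coords.shape[1] != 3:
            raise ValueError("coords must be a (V, 3) array")
        if coords.shape[0] == 0:
            raise ValueError("mask contains no voxels")
        lin = np.ravel_multi_index(coords.T, self.shape)
        if np.unique(lin).size != lin.size:
            raise ValueError("duplicate voxel coordinates in mask")
        order = np.argsort(lin)
        object.__setattr__(self, "coords", coords[order])
        # dense lookup grid: linear grid index -> in-mask index, -1 outside
        lookup = np.full(int(np.prod(self.shape)), -1, dtype=np.int64)
        lookup[lin[order]] = np.arange(lin.size)
        object.__setattr__(self, "_lookup", lookup)

    @classmethod
    def from_mask(
        cls,
        mask: np.ndarray,
        voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0),
        affine: np.ndarray | None = None,
    ) -> "MaskGeometry":
        mask = np.asarray(mask)
        if mask.ndim != 3:
            raise ValueError("mask must be 3-D")
        coords = np.argwhere(mask != 0)
        if coords.shape[0] == 0:
            raise ValueError("mask contains no voxels")
        return cls(
            shape=tuple(mask.shape),
            coords=coords,
            voxel_size=tuple(voxel_size),
            affine=np.eye(4) if affine is None else affine,
        )

    @property
    def V(self) -> int:
        """Number of in-mask voxels."""
        return self.coords.shape[0]

    def linear_index(self, coords: np.ndarray) -> np.ndarray:
        """Map grid coordinates to in-mask indices (-1 if outside mask)."""
        coords = np.atleast_2d(np.asarray(coords, dtype=np.int64))
        lin = np.ravel_multi_index(coords.T, self.shape)
        return self._lookup[lin]

    def _neighbors(self, voxel: int, offsets: np.ndarray) -> np.ndarray:
        cand = self.coords[voxel] + offsets
        ok = np.all((cand >= 0) & (cand < np.asarray(self.shape)), axis=1)
        idx = self.linear_index(cand[ok])
        return idx[idx >= 0]

    def neighbors6(self, voxel: int) -> np.ndarray:
        """In-mask face (6-connectivity) neighbours of ``voxel``."""
        return self._neighbors(voxel, _OFF6)

    def neighbors26(self, voxel: int) -> np.ndarray:
        """In-mask 26-connectivity neighbours of ``voxel``."""
        return self._neighbors(voxel, _OFF26)

    def adjacency26(self):
        """Sparse CSR 26-adjacency over in-mask voxels (symmetric, no self)."""
        from scipy import sparse

        rows, cols = [], []
        for v in range(self.V):
            nb = self.neighbors26(v)
            rows.append(np.full(nb.size, v))
            cols.append(nb)
        rows = np.concatenate(rows) if rows else np.empty(0, int)
        cols = np.concatenate(cols) if cols else np.empty(0, int)
        data = np.ones(rows.size, dtype=bool)
        return sparse.csr_matrix((data, (rows, cols)), shape=(self.V, self.V))

    def unmask(self, values: np.ndarray, background: float = 0.0) -> np.ndarray:
        """Scatter per-voxel values back onto the full 3-D grid."""
        values = np.asarray(values)
        if values.shape[0] != self.V:
            raise ValueError(f"expected {self.V} values, got {values.shape[0]}")
        vol = np.full(self.shape, background, dtype=np.result_type(values, float))
        vol[tuple(self.coords.T)] = values
        return vol


@dataclass(frozen=True)
class BoldSeries:
    """Masked BOLD time series: one row of length ``T`` per in-mask voxel."""

    data: np.ndarray
    geometry: MaskGeometry

    def __post_init__(self) -> None:
        data = np.asarray(self.data, dtype=np.float64)
        if data.ndim != 2:
            raise ValueError("data must be 2-D (V x T)")
        if data.shape[0] != self.geometry.V:
            raise ValueError(
                f"data has {data.shape[0]} rows but geometry has "
                f"{self.geometry.V} voxels"
            )
        if not np.all(np.isfinite(data)):
            raise ValueError("BOLD data contains non-finite values")
        object.__setattr__(self, "data", data)

    @property
    def V(self) -> int:
        return self.data.shape[0]

    @property
    def T(self) -> int:
        return self.data.shape[1]

    @property
    def zero_variance(self) -> np.ndarray:
        """Boolean flag per voxel: constant (zero-variance) time series."""
        return np.ptp(self.data, axis=1) == 0

    @property
    def n_zero_variance(self) -> int:
        return int(self.zero_variance.sum())


def load_bold(bold_path, mask_path) -> BoldSeries:
    """Load a 4-D BOLD NIfTI restricted to a 3-D binary mask.

    The mask is interpreted as nonzero = in-mask.  Voxels are ordered by
    ascending C-order linear index so that the ordering is reproducible
    across runs and implementations.

    Raises
    ------
    ValueError
        If the grids differ in shape or affine, or the mask is empty.
    """
    bold_img = nib.load(str(bold_path))
    mask_img = nib.load(str(mask_path))
    if bold_img.shape[:3] != mask_img.shape[:3]:
        raise ValueError(
            f"BOLD grid {bold_img.shape[:3]} does not match mask grid "
            f"{mask_img.shape[:3]}"
        )
    if not np.allclose(bold_img.affine, mask_img.affine, atol=1e-4):
        raise ValueError("BOLD and mask affines differ")
    mask = np.asarray(mask_img.dataobj) != 0
    if not mask.any():
        raise ValueError("mask contains no voxels")
    voxel_size = tuple(float(z) for z in bold_img.header.get_zooms()[:3])
    geometry = MaskGeometry.from_mask(
        mask, voxel_size=voxel_size, affine=bold_img.affine
    )
    data4d = np.asarray(bold_img.dataobj, dtype=np.float64)
    if data4d.ndim != 4:
        raise ValueError("BOLD image must be 4-D")
    data = data4d[tuple(geometry.coords.T)]
    return BoldSeries(data=data, geometry=geometry)


def write_map(values, geometry: MaskGeometry, path, background: float = 0.0) -> None:
    """Write per-voxel values to a NIfTI volume.

    Out-of-mask voxels are set to ``background`` (default 0).  Values are
    stored as float64 so that a reload reproduces them exactly, NaN included.
    """
    values = np.asarray(values, dtype=np.float64)
    if values.shape != (geometry.V,):
        raise ValueError(f"expected {geometry.V} values, got shape {values.shape}")
    vol = geometry.unmask(values, background=background)
    img = nib.Nifti1Image(vol.astype(np.float64), geometry.affine)
    img.header.set_zooms(geometry.voxel_size)
    nib.save(img, str(path))
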