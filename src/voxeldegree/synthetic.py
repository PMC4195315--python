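"""Synthetic phantoms with known region structure, and the six-node toy network.

The block phantom emulates what the degree-correction method assumes about
resting-state data: functional regions are sets of spatially adjacent voxels
sharing a coherent latent signal, pairs of regions may share an additional
"link" signal that functionally connects them, and every voxel carries
i.i.d. Gaussian noise.  Variance shares are controllable, so the expected
correlations have closed forms:

* within a linked parcel:  (a^2 + b^2) / (a^2 + b^2 + c^2)
* within an unlinked parcel:  a^2 / (a^2 + c^2)
* between linked parcels:  b^2 / (a^2 + b^2 + c^2)
* between unlinked parcels:  0

with a = sqrt(within_share), b = sqrt(link_share), c = sqrt(noise_share).

The toy network is the minimal example of the region-size effect: two
connected 2-voxel regions plus two connected 1-voxel regions.  Region-level
degree is 1 everywhere, yet voxel-wise unweighted degree is 3 in the large
regions and 1 in the small ones; the corrected metric restores uniformity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .connectivity import CorrelationMatrix
from .growing import ClusterMap
from .io import BoldSeries, MaskGeometry

__all__ = [
    "Phantom",
    "ToyNetwork",
    "make_block_phantom",
    "default_parcels",
    "toy_network",
    "make_multisubject",
    "make_icc_panel",
    "parcellation_labels",
    "recovery_ari",
]

DEFAULT_GRID = (8, 8, 4)
#: four cuboid parcels (corner, shape): two of 16 voxels, two of 4 voxels,
#: placed with gaps so no two parcels are 26-adjacent
DEFAULT_PARCELS = (
    ((0, 0, 0), (4, 2, 2)),
    ((0, 4, 0), (4, 2, 2)),
    ((5, 5, 0), (2, 2, 1)),
    ((5, 5, 2), (2, 2, 1)),
)
#: the two large parcels are linked to each other, as are the two small ones
DEFAULT_CONNECTIVITY = ((0, 1), (2, 3))

# Background voxels (in-mask, pure noise) matter: the adaptive threshold
# averages per-voxel neighbour-correlation levels over the *whole* mask, so
# weakly coherent tissue pulls T_a well below the coherent parcels'
# correlation level — exactly the regime the growing step assumes.  A mask
# containing only homogeneous parcels would put T_a slightly above the
# within-parcel correlations (the two-step filter keeps the upper tail) and
# fragment every cluster.  Each background voxel is its own 1-voxel region.


@dataclass(frozen=True)
class Phantom:
    """Synthetic BOLD series with ground-truth parcel labels."""

    series: BoldSeries
    labels: np.ndarray  # parcel id per in-mask voxel
    connectivity_spec: tuple[tuple[int, int], ...]
    params: dict = field(default_factory=dict)

    @property
    def geometry(self) -> MaskGeometry:
        return self.series.geometry


def default_parcels() -> tuple:
    """The standard test layout: 8x8x4 grid, parcels of 16/16/4/4 voxels."""
    return DEFAULT_PARCELS


def _parcel_coords(grid, parcels) -> list[np.ndarray]:
    """Expand (corner, shape) cuboids to coordinate arrays; check bounds/overlap."""
    grid = np.asarray(grid)
    seen = set()
    out = []
    for corner, shape in parcels:
        corner = np.asarray(corner)
        shape = np.asarray(shape)
        if np.any(corner < 0) or np.any(corner + shape > grid):
            raise ValueError(f"parcel at {tuple(corner)} does not fit the grid")
        coords = np.stack(
            np.meshgrid(
                *[np.arange(c, c + s) for c, s in zip(corner, shape)],
                indexing="ij",
            ),
            axis=-1,
        ).reshape(-1, 3)
        for c in map(tuple, coords):
            if c in seen:
                raise ValueError("parcels overlap")
            seen.add(c)
        out.append(coords)
    return out


def _assemble(
    geometry: MaskGeometry,
    labels: np.ndarray,
    connectivity,
    T: int,
    a: float,
    b: float,
    c: float,
    region_signals: np.ndarray,
    link_signals: np.ndarray,
    noise: np.ndarray,
    active: np.ndarray,
) -> BoldSeries:
    """Mix latent signals into voxel time series; inactive voxels are pure noise."""
    n_parcels = region_signals.shape[0]
    link_of = {p: [] for p in range(n_parcels)}
    for li, (p, q) in enumerate(connectivity):
        link_of[p].append(li)
        link_of[q].append(li)
    data = np.empty((geometry.V, T))
    for v in range(geometry.V):
        if not active[v]:
            data[v] = noise[v]
            continue
        p = int(labels[v])
        sig = a * region_signals[p]
        for li in link_of[p]:
            sig = sig + b * link_signals[li]
        data[v] = sig + c * noise[v]
    return BoldSeries(data=data, geometry=geometry)


def _phantom_geometry(grid, parcels, background, voxel_size):
    """Geometry plus per-voxel parcel index (-1 = background) and labels.

    With ``background=True`` the mask is the full grid and every background
    voxel is a distinct 1-voxel ground-truth region; otherwise the mask is
    the union of the parcels.
    """
    coords_per_parcel = _parcel_coords(grid, parcels)
    mask = np.zeros(grid, dtype=bool)
    parcel_vol = np.full(grid, -1, dtype=np.int64)
    for p, coords in enumerate(coords_per_parcel):
        mask[tuple(coords.T)] = True
        parcel_vol[tuple(coords.T)] = p
    if background:
        mask[:] = True
    geometry = MaskGeometry.from_mask(mask, voxel_size=voxel_size)
    parcel_idx = parcel_vol[tuple(geometry.coords.T)]
    labels = parcel_idx.copy()
    bg = parcel_idx < 0
    labels[bg] = len(parcels) + np.arange(int(bg.sum()))
    return geometry, parcel_idx, labels, coords_per_parcel


def make_block_phantom(
    grid=DEFAULT_GRID,
    parcels=DEFAULT_PARCELS,
    connectivity=DEFAULT_CONNECTIVITY,
    T: int = 300,
    within_share: float = 0.8,
    link_share: float = 0.15,
    noise_share: float | None = None,
    background: bool = True,
    voxel_size=(3.0, 3.0, 3.0),
    seed: int | None = 0,
    rng: np.random.Generator | None = None,
) -> Phantom:
    """Block phantom with coherent parcels embedded in a noise background.

    Defaults encode the standard recovery scenario: an 8x8x4 mask with four
    parcels of 16/16/4/4 voxels, within-region signal share 0.8, link share
    0.15 between the two parcel pairs, noise share 0.05, T = 300 time points
    (a typical resting-state scan length), the remaining mask voxels being
    independent unit-variance noise (1-voxel regions).  Set
    ``background=False`` to restrict the mask to the parcels themselves.
    """
    if noise_share is None:
        noise_share = max(0.0, 1.0 - within_share - link_share)
    rng = rng if rng is not None else np.random.default_rng(seed)
    geometry, parcel_idx, labels, _ = _phantom_geometry(
        grid, parcels, background, voxel_size
    )
    connectivity = tuple(tuple(pair) for pair in connectivity)
    region_signals = rng.standard_normal((len(parcels), T))
    link_signals = rng.standard_normal((max(len(connectivity), 1), T))
    noise = rng.standard_normal((geometry.V, T))
    series = _assemble(
        geometry,
        parcel_idx,
        connectivity,
        T,
        np.sqrt(within_share),
        np.sqrt(link_share),
        np.sqrt(noise_share),
        region_signals,
        link_signals,
        noise,
        active=parcel_idx >= 0,
    )
    return Phantom(
        series=series,
        labels=labels,
        connectivity_spec=connectivity,
        params={
            "T": T,
            "within_share": within_share,
            "link_share": link_share,
            "noise_share": noise_share,
            "background": background,
            "seed": seed,
        },
    )


@dataclass(frozen=True)
class ToyNetwork:
    """Six-node toy: regions A = {0,1}, B = {2,3}, C = {4}, D = {5}.

    Within-region pairs are connected, A and B are fully cross-connected,
    C and D are connected; there are no other edges.
    """

    adjacency: np.ndarray
    partition: np.ndarray

    n_nodes: int = 6

    def region_degrees(self) -> dict[int, int]:
        """Degree of each region in the collapsed region-level graph."""
        regions = np.unique(self.partition)
        deg = {}
        for r in regions:
            neighbors = set()
            members = np.flatnonzero(self.partition == r)
            for other in regions:
                if other == r:
                    continue
                om = np.flatnonzero(self.partition == other)
                if self.adjacency[np.ix_(members, om)].any():
                    neighbors.add(int(other))
            deg[int(r)] = len(neighbors)
        return deg


def toy_network() -> tuple[ToyNetwork, CorrelationMatrix, ClusterMap]:
    """The worked toy example, ready for the degree operations.

    Returns the toy network, its adjacency encoded as a correlation matrix
    (r = 0.9 on edges, 0 elsewhere) on a 6x1x1 grid, and the ground-truth
    per-seed cluster map (each voxel's cluster is its region).  With
    T_d = 0.5 the traditional unweighted degree is 3 for the large-region
    voxels and 1 for the small-region voxels, while the corrected degree is
    1 everywhere — matching the region-level graph, where every region has
    degree 1.
    """
    edges = [(0, 1), (2, 3), (0, 2), (0, 3), (1, 2), (1, 3), (4, 5)]
    adjacency = np.zeros((6, 6), dtype=np.int64)
    for i, j in edges:
        adjacency[i, j] = adjacency[j, i] = 1
    partition = np.array([0, 0, 1, 1, 2, 3])
    geometry = MaskGeometry.from_mask(np.ones((6, 1, 1), dtype=bool))
    values = np.where(adjacency.astype(bool), 0.9, 0.0)
    np.fill_diagonal(values, 1.0)
    matrix = CorrelationMatrix(
        values=values,
        flavor="temporal",
        geometry=geometry,
        degenerate=np.zeros(6, dtype=bool),
    )
    clusters = tuple(
        np.flatnonzero(partition == partition[i]) for i in range(6)
    )
    cluster_map = ClusterMap(
        clusters=clusters, flavor="combined", T_a_used=0.5, geometry=geometry
    )
    return ToyNetwork(adjacency=adjacency, partition=partition), matrix, cluster_map


def make_multisubject(
    phantom_params: dict | None = None,
    n_subjects: int = 10,
    n_scans: int = 3,
    between_subject_sd: float = 0.0,
    scan_noise_sd: float = 1.0,
    size_jitter: float = 0.0,
    link_density: float = 1.0,
    seed: int = 0,
) -> list[list[Phantom]]:
    """Per-subject, per-scan phantoms for test–retest emulation.

    Subject level (drawn once per subject, stable across scans): the latent
    region and link signals; the link variance share, scaled by
    ``1 + between_subject_sd * z`` with z standard normal; and, when
    ``link_density`` < 1, the connectivity topology itself — each candidate
    region pair of the phantom's connectivity list is realized with that
    probability.  These are the stable "traits" that reliability analyses
    should recover.

    Scan level (fresh per scan): i.i.d. noise with amplitude
    ``sqrt(noise_share) * scan_noise_sd``, and optional region-size jitter —
    each parcel voxel except the parcel's first is deactivated (replaced by
    pure unit-variance noise) with probability ``size_jitter``, making the
    *apparent* region size fluctuate between scans while the underlying
    connectivity trait does not.  With ``scan_noise_sd = 0`` the scan level
    is fully frozen and all scans of a subject are identical.
    """
    if n_scans < 3:
        raise ValueError("need at least 3 scans for test-retest emulation")
    params = dict(
        grid=DEFAULT_GRID,
        parcels=DEFAULT_PARCELS,
        connectivity=DEFAULT_CONNECTIVITY,
        T=300,
        within_share=0.8,
        link_share=0.15,
        noise_share=None,
        background=True,
        voxel_size=(3.0, 3.0, 3.0),
    )
    if phantom_params:
        params.update(phantom_params)
    if params["noise_share"] is None:
        params["noise_share"] = max(
            0.0, 1.0 - params["within_share"] - params["link_share"]
        )
    rng = np.random.default_rng(seed)

    geometry, parcel_idx, labels, coords_per_parcel = _phantom_geometry(
        params["grid"], params["parcels"], params["background"], params["voxel_size"]
    )
    first_voxel = np.zeros(params["grid"], dtype=bool)
    for coords in coords_per_parcel:
        first_voxel[tuple(coords[0])] = True
    protected = first_voxel[tuple(geometry.coords.T)] | (parcel_idx < 0)
    connectivity = tuple(tuple(pair) for pair in params["connectivity"])
    T = int(params["T"])
    a = np.sqrt(params["within_share"])
    c_base = np.sqrt(params["noise_share"])

    subjects: list[list[Phantom]] = []
    for s in range(n_subjects):
        trait = max(0.0, 1.0 + between_subject_sd * rng.standard_normal())
        link_share_s = min(params["link_share"] * trait, 0.99)
        b_s = np.sqrt(link_share_s)
        if link_density < 1.0:
            present = rng.random(len(connectivity)) < link_density
            connectivity_s = tuple(
                pair for pair, keep in zip(connectivity, present) if keep
            )
        else:
            connectivity_s = connectivity
        region_signals = rng.standard_normal((len(coords_per_parcel), T))
        link_signals = rng.standard_normal((max(len(connectivity_s), 1), T))
        scans: list[Phantom] = []
        frozen_noise = rng.standard_normal((geometry.V, T))
        for _ in range(n_scans):
            if scan_noise_sd == 0:
                noise = frozen_noise
                active = parcel_idx >= 0
                c = c_base
            else:
                noise = rng.standard_normal((geometry.V, T))
                drop = (rng.random(geometry.V) < size_jitter) & ~protected
                active = (parcel_idx >= 0) & ~drop
                c = c_base * scan_noise_sd
            series = _assemble(
                geometry,
                parcel_idx,
                connectivity_s,
                T,
                a,
                b_s,
                c,
                region_signals,
                link_signals,
                noise,
                active,
            )
            scans.append(
                Phantom(
                    series=series,
                    labels=labels,
                    connectivity_spec=connectivity_s,
                    params={
                        **{
                            k: params[k]
                            for k in ("T", "within_share", "noise_share")
                        },
                        "link_share": link_share_s,
                        "subject": s,
                        "seed": seed,
                    },
                )
            )
        subjects.append(scans)
    return subjects


def make_icc_panel(
    n_subjects: int = 10,
    n_voxels: int = 2000,
    between_sd: float = 1.0,
    noise_sd: float = 1.0,
    n_scans: int = 3,
    seed: int = 0,
) -> list[np.ndarray]:
    """Per-scan (n_subjects, n_voxels) maps with a known variance structure.

    Each map is ``mu_v + b_{s,v} + e_{s,v,scan}`` with the subject effect b
    of SD ``between_sd`` shared across scans and scan noise e of SD
    ``noise_sd`` fresh per scan.  The test–retest ICC between scan 1 and the
    mean of scans 2 and 3 then has the closed-form population value

        between_sd^2 / (between_sd^2 + 0.75 * noise_sd^2)

    since the two measurements carry error variances ``noise_sd^2`` and
    ``noise_sd^2 / 2`` (mean of two scans), averaging to 0.75 times the
    single-scan noise variance.
    """
    rng = np.random.default_rng(seed)
    mu = rng.standard_normal(n_voxels)
    b = between_sd * rng.standard_normal((n_subjects, n_voxels))
    return [
        mu[None, :] + b + noise_sd * rng.standard_normal((n_subjects, n_voxels))
        for _ in range(n_scans)
    ]


def parcellation_labels(cluster_map: ClusterMap) -> np.ndarray:
    """Label each voxel by the identity of its grown cluster.

    Voxels whose clusters contain exactly the same member set share a label;
    under perfect growing this reproduces the ground-truth parcels.
    """
    seen: dict[tuple, int] = {}
    labels = np.empty(cluster_map.V, dtype=np.int64)
    for i, c in enumerate(cluster_map.clusters):
        key = tuple(c.tolist())
        labels[i] = seen.setdefault(key, len(seen))
    return labels


def recovery_ari(cluster_map: ClusterMap, true_labels: np.ndarray) -> float:
    """Adjusted Rand index between grown-cluster labels and true parcels."""
    from sklearn.metrics import adjusted_rand_score

    return float(
        adjusted_rand_score(np.asarray(true_labels), parcellation_labels(cluster_map))
    )
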