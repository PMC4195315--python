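# voxeldegree

Region-size-corrected degree metrics for voxel-wise functional brain
networks.

## The problem

In voxel-wise resting-state fMRI network analysis, every gray-matter voxel
is a node and two voxels are connected when the Pearson correlation of
their BOLD time series passes a connectivity threshold T_d.  Degree
centrality — the number (or summed weight) of a voxel's connections — is
then used to map network hubs.  But a voxel's degree scales with the size
of the functional region it belongs to and with the sizes of the regions it
connects to: a region of m voxels fully connected to a region of n voxels
gives each of its voxels degree (m − 1) + n even though, at the region
level, it has a single neighbor.  Large regions (visual cortex,
precuneus/posterior cingulate) therefore look like hubs regardless of their
actual region-level connectivity.

`voxeldegree` implements a data-driven correction.  For each voxel i it
estimates the voxel's functional region C_i by adaptive-threshold region
growing, then computes

    D_RSE(i) = Σ_j w(i,j) · f(i,j) · g(i,j) / s(i,j)

where f(i,j) = 1 iff r(i,j) ≥ T_d (the connection indicator),
g(i,j) = 0 when j ∈ C_i (drops within-region self-connections),
s(i,j) = |{k ∈ C_j \ C_i : r(i,k) ≥ T_d}| (divides each cross-region
connection by the effective size of the connected region), and the weight
w is 1 (U), r (W), r² (WS) or atanh r = ½ln[(1+r)/(1−r)] (WF), giving the
corrected counterparts U_RSE, W_RSE, WS_RSE, WF_RSE of the four standard
degree metrics.

Region estimation runs in six stages: (1) temporal correlation matrix;
(2) spatial correlation matrix (correlations between whole-brain
connectivity fingerprints); (3) adaptive threshold T_a per matrix — each
voxel's face-neighbor correlations are filtered twice (drop those below the
matrix-wide mean positive correlation, then those below the survivors'
mean) and averaged, and T_a is the mean over voxels; (4) region growing
from every seed over 26-connectivity with criterion r(seed, j) ≥ T_a;
(5) per-seed intersection of the temporal and spatial clusters; (6) degree
computation over a T_d sweep (0.15–0.50, step 0.05 by default).  Quality of
the growing is quantified by the region-growing error rate (fraction of
voxel pairs with asymmetric cluster membership) and by agreement of the
type I (own-cluster size M_i = |C_i|) and type II (containing-cluster count
N_i) maps; test–retest reliability of degree maps is measured voxel-wise as
the intra-class correlation ICC(A,1) between scan 1 and the mean of scans 2
and 3 across subjects.

Who it is for: researchers computing voxel-wise degree/functional
connectivity density maps from preprocessed resting-state BOLD data who
want hub estimates that are not driven by functional region size.  Input is
a preprocessed 4-D NIfTI plus a binary gray-matter mask (no preprocessing
is performed here), or any voxel × voxel correlation matrix with geometry.

## Worked example

The minimal network exhibiting the size effect: regions A and B of two
voxels each (connected to each other), regions C and D of one voxel each
(connected to each other).  Every region has region-level degree 1, so no
region is a hub.

```bash
$ voxeldegree toy
Six-node toy network (T_d = 0.5)
 voxel       region      U  U_RSE
     0 A (2 voxels)    3.0    1.0
     1 A (2 voxels)    3.0    1.0
     2 B (2 voxels)    3.0    1.0
     3 B (2 voxels)    3.0    1.0
     4  C (1 voxel)    1.0    1.0
     5  D (1 voxel)    1.0    1.0
region-level degrees: {0: 1, 1: 1, 2: 1, 3: 1}
```

Traditional unweighted degree U is 3 for every large-region voxel (one
within-region connection plus two cross-region ones) but 1 for the
small-region voxels — a spurious threefold hub disparity.  The corrected
U_RSE drops the within-region connection and divides each A–B connection by
the connected region's size (2), restoring degree 1 everywhere, exactly the
region-level answer.

The same pipeline as a library, statsmodels-style:

```python
from voxeldegree import VoxelDegreeModel, make_block_phantom

phantom = make_block_phantom(seed=0)          # 8x8x4 grid, parcels 16/16/4/4
results = VoxelDegreeModel(phantom.series).fit()
print(results.summary())                      # T_a, RGER, degree table
u_rse = results.degree_map("U", 0.15, corrected=True)
```

or from the shell on NIfTI inputs:

```bash
voxeldegree run --bold bold.nii.gz --mask mask.nii.gz --out out/
```

which writes the T_a reports, the type I/II cluster-size maps, the RGER,
one NIfTI map per (metric, T_d, corrected) and a hash manifest.  Stage
subcommands (`correlate`, `threshold`, `grow`, `evaluate`, `degree`,
`reliability`, `simulate`) expose the intermediates for caching and
resumption.

## Documentation

`docs/methods.md` describes the model, the synthetic phantoms, all
parameter choices and known limitations.
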