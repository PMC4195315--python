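# Methods

## Model and assumptions

The package treats a masked 4-D BOLD acquisition as a weighted graph on
in-mask voxels with edge weights r(i, j), the Pearson correlation of the
preprocessed time series.  It assumes:

* the data are already preprocessed (motion-corrected, nuisance-regressed,
  band-pass filtered) and in a common grid with the mask;
* functional regions are sets of spatially contiguous voxels with coherent
  spontaneous signal, so within-region correlations concentrate above the
  correlations of a voxel with unrelated tissue;
* correlations are static over the scan (no dynamic connectivity).

Degree metrics count (U) or weight (W: r, WS: r², WF: atanh r) the
suprathreshold connections of each voxel.  The corrected variants remove
the two region-size channels separately: the g term removes connections to
the voxel's own estimated region (the "(m − 1)" within-region term), and
the s term divides each remaining connection by the number of voxels of the
connected region that are themselves suprathreshold-connected to the source
voxel (collapsing the "n" cross-region term to approximately the number of
connected regions).  Whenever a term survives (f = 1, g = 1), the target
voxel j is itself a member of C_j \ C_i connected to i, so s ≥ 1 and the
division is always defined; the implementation asserts this invariant.

## Region estimation

Two correlation structures are grown and intersected:

* **temporal** — raw time-series correlations;
* **spatial** — for each pair (i, j), the correlation of their whole-brain
  temporal-correlation maps.  The self-positions i and j are removed from
  both maps before correlating; otherwise the two diagonal 1s and the
  shared r(i, j) entry would leak trivial agreement.  (The source procedure
  does not specify this; removal is the conservative choice.)  Negative
  temporal correlations are kept in the maps (no clipping).

**Adaptive threshold T_a.**  For each voxel, the correlations with its
up-to-six in-mask face neighbors are filtered in two steps: (1) drop
negatives and values below the mean positive correlation of the whole
matrix (upper triangle, diagonal excluded — including the diagonal 1s
would bias the level upward); (2) drop survivors strictly below the
survivors' mean — ties survive, matching a strict reading of "lower than
the average".  The voxel's threshold is the mean of the final survivors;
voxels with no step-1 survivor are excluded from (not imputed into) the
final average, and T_a is the mean over the remaining voxels.  The mean
positive correlation is recomputed per matrix (temporal and spatial
flavors get independent T_a values).  Step 2 can never lower a voxel's
threshold below the step-1 mean.  A floating-point corner case is handled
explicitly: when all survivors are (nearly) equal, their mean can round
above the maximum and empty the step-2 set; the step-1 mean is returned.

**Region growing.**  From every seed i, 26-connected neighbors j of the
current cluster are added while r(i, j) ≥ T_a, to a fixed point.  The
criterion always correlates the candidate with the original seed — the
correlation matrix does not change across iterations, so the result is the
26-connected component of {j : r(i, j) ≥ T_a} ∪ {i} containing i and is
independent of visit order.  Clusters of different seeds may overlap or
disagree; no global parcellation is enforced.  The temporal and spatial
clusters of each seed are intersected (the combined map); intersections may
be disconnected and are kept as-is, since the degree formulas use only
membership.

**Quality indices.**  RGER counts unordered pairs {i, j} where exactly one
of j ∈ C_i, i ∈ C_j holds, divided by V(V−1)/2.  The type I map is
M_i = |C_i|; the type II map N_i counts all clusters containing i,
*including C_i itself*, so that perfectly symmetric growing yields M = N
exactly (Σ M = Σ N always — both count membership incidences).  Counting
only other clusters would force M = N + 1 at perfection; the inclusive
count is the reconciliation adopted here and this subtlety is worth knowing
when comparing against other descriptions of the index.

## Map preparation and reliability

Degree and cluster-size maps are z-scored (population SD, ddof = 0 —
recorded in output metadata and configurable) and then smoothed with an
8 mm FWHM Gaussian (σ = FWHM/(2√(2 ln 2)) per axis in voxel units),
z-score first.  Smoothing is mask-normalized: the zero-filled volume and
the binary mask are both smoothed with a zero-padded kernel and divided, so
constants are preserved exactly and no out-of-mask value bleeds in.

The intra-class correlation is computed from the two-way ANOVA mean squares,
vectorized across voxels; the default variant is ICC(A,1) (two-way model,
absolute agreement, single measurement — numerically identical to
ICC(2,1)), with ICC(C,1) available.  Test–retest reliability uses scan 1
versus the elementwise mean of scans 2 and 3 as the two measurements,
voxel-wise across subjects.  Voxels with zero across-subject variance in
either measurement are reported NaN and excluded from summary means.
`pingouin.intraclass_corr` serves as an independent oracle in the tests;
the in-package implementation exists because voxel-wise maps need 10³–10⁵
ICCs at once.

## Synthetic data

`make_block_phantom` emulates the structure the method assumes: cuboid
parcels share a per-parcel latent signal (amplitude √within_share), linked
parcel pairs share an additional link signal (√link_share), and every voxel
carries i.i.d. Gaussian noise.  Expected correlations have closed forms
(e.g. between linked parcels b²/(a²+b²+c²)), which the tests verify by
simulation at T = 10⁴.  Defaults — the standard recovery scenario used
throughout the tests and the acceptance script — are an 8×8×4 grid, two
16-voxel and two 4-voxel parcels (the two pairs linked), within share 0.8,
link share 0.15, noise share 0.05, T = 300 time points (a typical
resting-state scan length at TR = 2 s).

The mask deliberately includes the non-parcel grid voxels as pure-noise
background, each its own 1-voxel ground-truth region.  This is not
decoration: T_a averages per-voxel neighbor-correlation levels over the
whole mask, so weakly coherent tissue pulls T_a below the coherent parcels'
correlation level — the regime the growing step assumes.  A mask containing
only homogeneous parcels puts T_a slightly *above* the within-parcel
correlations (the two-step filter keeps the upper tail of a narrow
distribution) and fragments every cluster; real gray-matter masks always
contain low-coherence voxels.

`make_multisubject` generates per-subject, per-scan phantoms.  Stable
subject traits, drawn once per subject: the latent signals, a link-strength
multiplier (1 + between_subject_sd·z), and — with link_density < 1 — the
connectivity topology itself (each candidate region pair realized with that
probability).  Fresh per scan: the noise (amplitude scaled by
scan_noise_sd; scan_noise_sd = 0 freezes the scan level entirely, making
scans identical) and apparent-region-size jitter: with probability
size_jitter each non-anchor parcel voxel is deactivated for that scan
(replaced by pure noise), so the *apparent* region size fluctuates while
the underlying connectivity does not.  This is the condition under which
region-size correction should improve test–retest reliability: traditional
degree inherits the size fluctuations as scan noise, while the corrected
degree reads the stable topology.  The reliability comparison uses within
share 0.65, link share 0.3, noise share 0.05, link density 0.5, size
jitter 0.3 and T_d = 0.2 — the link share is raised and T_d chosen above
the r-sampling noise tail (sd ≈ (1−ρ²)/√T ≈ 0.057 at T = 300) so that
background false-positive connections, which enter the corrected metrics
at full weight (s = 1 for singleton background clusters), stay negligible
(≈0.06 expected per voxel) while cross-region connections remain
detectable.

`make_icc_panel` simulates per-scan subject maps μ_v + b_{s,v} + e directly,
with the subject effect shared across scans; the test–retest ICC between
scan 1 and the mean of scans 2–3 then has population value
σ_b²/(σ_b² + 0.75 σ_e²) (error variances σ_e² and σ_e²/2, averaging to
0.75 σ_e²).  The ANOVA estimator carries a finite-sample negative bias of
roughly 0.75(1−ICC)/n; with n = 10 subjects the check is run at
σ_b = 1, σ_e = 0.5 (population value 0.842), where the bias (~0.03) is well
inside the ±0.05 verification band.

What passing these tests does and does not show: the phantoms have
block-homogeneous regions, Gaussian AR(0) signals, no hemodynamic
convolution, no physiological or motion artifacts, no spatial
autocorrelation of noise, and region/background contrast far cleaner than
cortex.  Success here validates the algorithmic machinery (thresholding,
growing, correction algebra, ICC), not the magnitude of the correction's
benefit on real data.

## Numerical choices

* Voxel ordering is ascending C-order linear index of the grid everywhere;
  outputs are pure functions of (inputs, config, seed).
* Zero-variance voxels stay in the mask but all their correlations
  (including the diagonal) are 0, never NaN, so they cannot pass any
  positive threshold.
* Correlation matrices are computed in row blocks (configurable
  `block_size`); blocked and full evaluation agree to ~1e-15 and the
  blocked spatial correlation uses closed-form moment corrections for the
  two removed positions rather than materializing reduced vectors.
* Spatial-correlation pairs whose reduced fingerprints have (numerically)
  zero variance get correlation 0, mirroring the zero-variance rule.
* The connection indicator is inclusive (r ≥ T_d, r ≥ T_a), following the
  displayed update rule rather than the surrounding prose ("larger than").
* The self term j = i is excluded from all degree sums (it would add a
  constant to every voxel; the corrected metrics drop it through g
  regardless); a strict-formula mode (`include_self=True`) is available.
* WF raises on |r| = 1 (duplicated series ⇒ infinite Fisher-z weight)
  rather than clamping.
* The default T_d sweep is 0.15–0.50 in steps of 0.05.  Traditional metrics
  are monotone non-increasing in T_d; the corrected metrics are *not* —
  raising T_d can shrink s(i, j) and increase a surviving term's 1/s
  weight — so monotonicity is only asserted for the traditional family.

## Problem sizes

The test suite and acceptance script run at V = 256 voxels (8×8×4 grid),
V = 1000 for the blocked-equivalence check, T = 150–300 time points,
10 subjects × 3 scans for reliability, and V ≤ 50 for brute-force oracle
comparisons — sizes at which every stage, including the O(V³) corrected
degree and the O(V²) pair enumerations, completes in seconds while
exercising the same code paths as whole-brain data (where V ≈ 5×10⁴ and the
blocked evaluation matters).

## Known limitations

* Whole-brain V ≈ 5×10⁴ implies a ~20 GB float64 correlation matrix; the
  blocked computation bounds working memory but the full matrix is still
  materialized.  Out-of-core storage is not implemented.
* The corrected degree loop is O(V³) worst case; at whole-brain scale it
  relies on connection sparsity at practical T_d values and would benefit
  from a sparse implementation.
* No gray-matter tissue priors ship with the package; any binary mask is
  accepted.
* Group statistics (ANOVA across thresholds, paired tests between metric
  families, FDR-corrected contrasts) are out of scope; the package stops at
  per-subject maps and ICC summaries.
* Combined clusters may be disconnected after intersection; they are used
  as membership sets only.
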