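# Methods

## Model and procedure

`rfnclust` treats resting-state functional connectivity analysis as a tree
problem.  The pipeline is, in order:

1. **Connectivity.**  Per subject, Pearson correlations CC between all
   in-mask voxel time courses; entries with CC ≥ τ kept verbatim (boundary
   inclusive), the rest set to 0.  Thresholded matrices are averaged
   arithmetically over subjects (sub-threshold entries contribute 0 to the
   mean; an alternative that drops them from the denominator sits behind the
   `drop_zeros` flag).  Distances are d = 1 − CC where the mean CC is
   positive and a sentinel d_max elsewhere.
2. **Clustering.**  Size-weighted average linkage (UPGMA): the distance
   between clusters is the mean over all cross-cluster leaf-pair distances,
   maintained with the Lance–Williams average update.  Ties are broken by the
   lexicographically smallest (min id, max id) pair, which makes node ids and
   merge order fully deterministic.  UPGMA is reducible, so merge heights are
   monotone; the cut routine nevertheless checks monotonicity and falls back
   to node-height order with a warning if a deserialized tree violates it.
3. **Extraction.**  Cut at k_initial; clusters with S > s_max are re-cut
   inside their own subtree at a count divided by the halving factor
   (floored at 2); clusters with s_min ≤ S ≤ s_max become candidate
   networks.  Every decision is logged with iteration, parent node and
   status; oversize clusters surviving max_depth are emitted flagged rather
   than dropped.
4. **Significance.**  A cluster (S, c) with minimum internal mean CC c is
   significant iff S ≥ max(size_floor, S_min(c)).  S_min(c) is assembled in
   two steps: (a) the lower envelope of the one-sample t versus mean-CC
   scatter over voxel pairs — minimum t per equal-width CC bin (default
   0.01), forced non-decreasing across bins, converted to one-sided p at
   df = N − 1 — gives the voxel-wise p bound for c; (b) a Monte-Carlo
   simulation draws white Gaussian noise on the mask's bounding grid,
   smooths it to the data's estimated FWHM, standardizes over in-mask
   voxels, thresholds at the one-sided z quantile, and records the maximum
   connected supra-threshold cluster per iteration; S_min is the smallest
   extent whose exceedance fraction is ≤ α.  All CC-grid points share one
   simulation run (same noise fields, different thresholds), so the curve is
   internally consistent; monotonicity is enforced by a running minimum.
5. **Dissection.**  Within a network's subtree, nodes are visited in
   descending height (the successive cuts).  A significant cluster splitting
   into two significant clusters is a dissociable node.  The sub-networks
   are the significant clusters of the final cut, whose level is chosen
   where the inconsistency-coefficient curves of the two largest networks
   first cross (discrete sign change; the crossing value is linearly
   interpolated).  The inconsistency coefficient of a link is
   (h − mean L)/std L over the link set L containing the node and its
   internal children (depth 2, sample std, 0 when the std vanishes) — the
   convention of the standard hierarchical-clustering toolboxes, which the
   tests cross-check against an independent enumeration and against scipy.
6. **Reporting.**  Sub-networks are re-assembled into a sub-dendrogram:
   leaves at their own merge heights, internal heights equal to full-tree
   cophenetic distances (the height at which two groups join).  Since
   cophenetic distances are ultrametric, running average linkage on them
   reconstructs the induced topology exactly.  Leaves are labeled in
   ascending height order.  Outputs: plain-text node lists (one line per
   merge: id, height, children, child sizes), TSV tables (size, height,
   focal point, CC_min/avg/max, IC), NIfTI label maps, and Newick trees with
   branch lengths equal to height differences.

## Parameters

| parameter | default | meaning |
|---|---|---|
| τ (tau) | 0.3 | per-subject CC threshold; d = 1 − CC ≤ 0.7 |
| d_max | 9.0 | sentinel distance for unconnected pairs; any value > 2 works |
| k_initial | 64 | whole-tree cut count of the first extraction iteration |
| s_min / s_max | 50 / 5000 | voxel-size band for candidate networks |
| α (alpha_fwer) | 0.01 | family-wise error rate for cluster significance |
| size_floor | 12 | minimum extent of a significant cluster (voxels) |
| n_iterations | 10⁴ | Monte-Carlo iterations for the extent simulation |
| connectivity_rule | faces | voxel adjacency for null clusters (most conservative) |
| ic_depth | 2 | levels in the inconsistency link set |
| envelope bin width | 0.01 | CC bin for the lower-envelope estimator |

The desk-scale default of 10⁴ simulation iterations estimates the α = 0.01
tail from ~100 exceedances; large-scale analyses use 10⁶, which narrows the
S_min confidence band by an order of magnitude.  The demo pipeline configs in
the examples and tests scale k_initial and the size band to their ~600-voxel
grids (k_initial = 8, 50 ≤ S ≤ 300), since a 64-cut of a 600-leaf tree would
operate at a different granularity than the same cut of a 13k-leaf tree.

## The synthetic generator

Every module in a rooted hierarchy carries a band-limited (< 0.08 Hz)
unit-variance latent course; a voxel of leaf m receives
Σ w_a·s_a(t) over ancestors a, plus white noise.  Expected correlations
follow in closed form as shared over total variance, so target CCs translate
directly into mixing weights (`nested_block_spec` solves the two-level case).
The generator reproduces: multi-subject sampling variability, the
resting-state frequency band of the signal, nested block correlation
structure, and optional masked spatial smoothing.  It does **not** emulate
physiological noise, head motion, spatial heterogeneity of noise, or
inter-subject anatomical variability — so passing recovery tests demonstrate
algorithmic correctness under the stated correlation model, not robustness
to real-world artifacts.  Voxel noise is deliberately white (no temporal
filtering), keeping the null distribution of Pearson r exactly at T − 2
degrees of freedom, which the null-calibration tests exploit.

## Numerical choices

- Matrices are stored condensed (upper triangle) at single precision;
  averaging accumulates in double so the result is independent of subject
  order.  Tree heights are double precision internally, serialized at six
  decimals.
- The low-pass filter is zero-phase in the frequency domain with a raised-
  cosine taper over [f_c, 1.25·f_c]; zero phase preserves inter-voxel
  correlation structure.
- Masked smoothing renormalizes the Gaussian kernel over in-mask support
  (smooth(f·m)/smooth(m)), so no mass is borrowed from outside the mask and
  the in-mask mean is conserved.
- Smoothness estimation uses the variance-of-differences formula
  FWHM_i = Δx_i·√(−2 ln 2 / ln(1 − s²_diff/(2 s²))) per axis, averaged over
  timeframes, with axes whose ratio leaves the log undefined reporting 0;
  axes are combined by geometric mean (the isotropic-equivalent convention
  of extent-threshold simulators).
- Cut ties (equal heights) are resolved by removing the later merge first,
  which keeps the removed set upward-closed for monotone trees.
- The skewness/kurtosis screen reports bias-uncorrected sample skewness and
  Fisher *excess* kurtosis (normal ≈ 0); the convention is stated in the
  API docs because published ranges for these moments vary by convention.
- On null data the empirical t-vs-CC envelope is degenerate (almost no pair
  survives τ), so calibration experiments build the CC → p map analytically:
  P(mean thresholded CC ≥ c) ≤ 1 − (1 − q)^N with q the null Pearson tail
  at τ.  This union bound is conservative, which is the safe direction for a
  type-I-error check.

## Design choices where the design was open

- Thresholding is applied in CC space per subject *before* averaging, so
  averaged values well below τ exist in the mean matrix; the sentinel
  replacement happens after averaging, in distance space.  Both orderings
  are defensible; this one reproduces the characteristic shape of averaged-
  CC histograms with mass below τ.
- "Focal point" is the unweighted centroid of member voxels in mm.
- The extraction count k_initial counts raw cut clusters, before the size
  filter.
- The IC-curve x-axis is the cut level within each network's own subtree,
  and the curve intersection uses the first discrete sign change with linear
  interpolation for the crossing value.
- Anatomical labeling of clusters is out of scope; tables carry coordinates
  only.  Newick export is provided beyond the plain node list for
  interoperability with tree tooling.

## Problem sizes

The test suite and the acceptance script run the full pipeline at 600 voxels,
20 subjects and T = 290, with 1000–2000 Monte-Carlo iterations, 200-replicate
type-I calibration on a 144-voxel mask, and oracle comparisons on random
trees up to n = 50.  These sizes keep the whole suite under a minute of
clustering work while leaving every algorithmic path identical to a
full-scale run; only n (voxels, subjects, iterations) changes.

## Known limitations

- UPGMA is maintained as a full dense distance matrix (O(n²) memory,
  O(n³)-ish time with vectorized scans): fine to ~10⁴ voxels, not beyond.
- The sub-network count at the IC-selected cut level depends on the cut
  level in a stepwise way; on very clean synthetic data the IC curves cross
  early (uniform planted blocks have low internal IC), so deep sub-sub-
  structure is only reached by lowering the cut level manually.
- The FWER simulation standardizes each noise field by its in-mask sample
  moments; with heavy smoothing on small masks the effective number of
  independent samples is low, which fattens the tail relative to an
  oracle-standardized field.  This is conservative (larger S_min).
- Split-half variability utilities expose the comparison machinery
  (histograms, per-half criterion curves) but leave the interpretation to
  the caller.
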