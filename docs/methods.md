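# Methods notes

## Pipeline model and assumptions

The analysis assumes a single cell per movie whose polarity axis is well
approximated, in 2D after maximum projection, by the major axis of the
mask's moment-equivalent ellipse. All geometry is 2D: depth (z) structure
is collapsed by the MIP, so the method cannot resolve distributions along
the optical axis. Segmentation is an input (masks are consumed, not
produced); so are the event annotations (elongation onset, pre-division
frame), the apex side, and the division-plane point — all of which are
manual in practice and recorded in the dataset manifest.

Axis convention: arrays are (frame, z, row, col), row index increasing
downward; orientation θ is in degrees in [0, 180), measured
counter-clockwise (on the displayed image) from the column axis, so a
vertical axis is 90°.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| k | 10 | normalized time points between onset and pre-division |
| L | 110 | standard profile length, px (configurable) |
| n_trees | 500 | random-forest size |
| m_try | 10 | features tried per split |
| alpha | 0.01 | Tukey–Kramer significance level |
| rf seed | 20231218 | default forest RNG seed |

Time selection uses nearest-frame rounding (round-half-up on the real
grid); no temporal interpolation. Windows shorter than k frames select
duplicates with a warning rather than failing — observed elongation
durations vary several-fold between movies.

Profile standardization: linear resampling (exact endpoints) followed by
z-scoring with the population SD (divisor n), so "SD = 1" holds exactly
on the output. Zero-variance profiles raise an error (an all-flat profile
indicates an empty or saturated cell, or a noise-free uniform synthetic
probe). Flatness is judged relative to the data scale (sd ≤ 1e-12 ×
max|x|).

## Numerical choices

- **Rotation** uses an affine transform about the image centre on a
  canvas expanded to the rotated bounding box, bilinear for intensity and
  nearest-neighbour (0.5-coverage re-binarized) for the mask. Intensity
  is interpolated as a normalized convolution — I·M and M are both
  rotated bilinearly and divided — so pixels near the cell edge are not
  diluted by the zero background. At identity rotation this reduces to
  plain masking; across planted orientations {0°, 17°, 30°, 45°} the
  resulting standardized profiles agree within 0.011 z-units (tested
  bound 0.1).
- **Ward clustering** uses `scipy.cluster.hierarchy.linkage(method="ward")`
  on the raw row/column vectors, which is the ward.D2 variant: squared
  Euclidean dissimilarities in the Lance–Williams recursion, heights
  reported as the square root of the merge cost. Tie-breaking follows
  scipy's nearest-neighbor-chain order; ties have measure zero for
  continuous data. The test suite checks agglomeration against an
  exhaustive O(n³) Lance–Williams reference with lexicographic
  tie-breaking on random matrices.
- **Boundary rule**: the two-cluster labels ordered tip→base are reduced
  to the two-segment split minimizing the number of disagreeing
  positions, ties toward the smaller apical segment; the residual
  disagreement count is reported as `contiguity_violations`. For
  contiguous labels this is the obvious boundary.
- **Cluster naming**: the position cluster containing the tip is
  "apical"; the feature group with the larger mean over basal positions
  is "Group 1" (basal-high features).
- **Random forest**: scikit-learn classifier, trees grown to purity,
  bootstrap of size L, OOB votes for the confusion matrix. Raw mean
  decrease in Gini is the per-tree unnormalized impurity decrease
  averaged over the forest; the reported per-structure numbers rescale to
  percent of the total and average over each replicate's time points,
  giving one value per (structure, replicate) — n = 3 per structure in
  the full design. Both raw and percent importances are emitted.
- **Tukey–Kramer** uses the studentized-range distribution with the
  unequal-n correction (scipy's implementation); the compact letter
  display is an insert–absorb construction. statsmodels' pairwise Tukey
  HSD serves as an independent reference in the tests.
- **Division plane**: % from tip is a pure ratio, invariant to
  translation and scaling of the axial coordinates; the summary uses the
  sample SD (divisor n−1) and compares the mean with boundary/2.

## Synthetic data: what it emulates, and what it does not

The generator renders a capsule (stadium) cell of width 40 px elongating
linearly from 120 to 220 px over the k frames, at a fixed random in-plane
angle per movie, extruded over 5 z-slices with a hemispheric intensity
falloff normalized so the noiseless MIP equals the 2D render exactly.
Each probe carries a closed-form axial density in relative coordinate
u ∈ [0, 1] (tip → base), constant across frames — distribution patterns
are established at elongation onset and maintained, with a planted
compartment boundary fraction b (default 0.436):

- `basal_gradient`: baseline + amplitude · logistic((u − b)/w). Vacuolar
  membranes: amplitude 1.0, w = 0.02 (sharp, high-contrast — the planted
  boundary signal); actin: amplitude 0.35, w = 0.08 (weak, gradual).
- `apical_band`: Gaussian bump at u = b/2 (the apical compartment's
  midpoint), microtubules: amplitude 0.8, σ = 0.05.
- `uniform`: mitochondria.

Noise has three deliberately distinct components:

1. **Detector noise**: additive Gaussian per voxel, SD = 10% of the
   largest probe's dynamic range — probe-independent, as for a single
   detector, so weaker-contrast probes have lower SNR.
2. **Axial speckle**: multiplicative, smoothly correlated modulation
   along the axis (SD 5%, correlation length 0.03 u) per frame, modelling
   organelle clumpiness. Unlike voxel noise it survives averaging across
   the cell width and therefore sets the per-profile noise floor.
3. **Biological variability**: the density anchor shifts per movie
   (actin 0.03, microtubules 0.02, vacuole 0.005 SD in u) and, for actin,
   additionally per time point (0.04) — actin reorganizes on the imaging
   timescale while vacuolar architecture is stable.

These choices matter for what the planted ground truth *means*: the
boundary is recoverable because the vacuolar step is the sharpest,
highest-SNR, most reproducible transition, and the importance ranking is
decidable because the speckle floor makes the gentle actin gradient
locally non-monotone at the boundary while leaving the vacuolar step
clean. Division planes are planted at fraction ~N(b/2, 0.0215) on the
last frame's axis, one per movie (n = 12 in the default design).

Not emulated: optics (PSF, spectral bleed-through, photobleaching),
segmentation errors (masks are the exact noiseless support), irregular
cell shapes, z-resolved structure, and any temporal trend in the
distributions. Passing tests therefore demonstrate correctness of the
measurement chain and the recoverability of planted signals under
realistic noise — not robustness to segmentation quality or shape
pathology in real data.

## Problem sizes in tests and the acceptance script

The end-to-end recovery tests run the full default design (12 movies ×
10 frames, ~244² px canvas, 5 z-slices) for seeds 1–20 in memory; disk
round-tripping is exercised separately on a reduced geometry (60→100 px)
because TIFF round-trips are bit-exact for the float32 stacks either way.
The acceptance script runs one full-design pipeline at the given seed.

## Known limitations

- The moment-ellipse orientation degrades for nearly isotropic masks;
  such cells are flagged degenerate and require an explicit angle.
- Boundary location inherits the flatness of the Ward two-cluster
  objective: when no probe carries a sharp transition, the split can
  wander several positions at fixed noise. The `contiguity_violations`
  count is the diagnostic to watch.
- OOB error with ~110 samples is quantized in steps of 0.9 points.
- Exact replication of other random-forest implementations' RNG streams
  is not possible; forest results are reproducible only within this
  package for a fixed seed.
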