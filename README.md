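# zygopolar

Quantitative analysis of intracellular polarity along the apical–basal
axis of elongating plant zygotes, from time-lapse 3D fluorescence stacks.

After fertilization the *Arabidopsis thaliana* zygote elongates and
divides asymmetrically into an apical and a basal cell. Different
intracellular structures — actin filaments, mitochondria, cortical
microtubules, vacuolar membranes — distribute unevenly along the
apical–basal axis during this elongation, and the question this package
addresses is whether their joint distribution compartmentalizes the cell
into an apical and a basal domain, where that boundary sits, which
structure carries the signal, and how the boundary relates to the
position of the asymmetric division plane. It is written for cell
biologists and image analysts working with single-cell time-lapse data
where cell size, shape, orientation, and probe brightness all vary
between samples and must be normalized away before profiles can be
compared.

## Method

For each movie, frames between elongation onset (T = 0) and the frame
just before division (T = k−1, default k = 10) are selected at equal
intervals. Per selected frame:

1. **MIP**: maximum intensity projection over z.
2. **Axis fit**: the binary cell mask's moment-equivalent ellipse; the
   major axis (θ = ½·atan2(2μ₁₁, μ₂₀−μ₀₂)) defines the apical–basal axis.
3. **Orientation**: rotation by 90°−θ (apex up, from a per-movie apex
   annotation), background zeroed outside the rotated mask.
4. **Axial profile**: mean intensity of mask pixels per row, tip → base.
5. **Standardization**: linear resampling to L = 110 points and z-scoring
   to mean 0, population SD 1 — removing cell length and probe gain.

The profiles form a positions × features matrix **X** (110 × 120 for
4 probes × 10 time points × 3 replicates). Rows are clustered with Ward's
minimum-variance linkage on Euclidean distances (the ward.D2 variant) and
cut at two clusters; the apical/basal boundary is the two-segment split
minimizing label disagreement, reported as % of cell length from the tip.
A random forest (500 trees, 10 features per split) is then trained on the
cluster labels; accuracy is the out-of-bag error, and structures are
ranked by mean decrease in Gini impurity, aggregated per replicate and
compared with the Tukey–Kramer test (p < 0.01, compact letter display).
Division planes annotated on the division frame are mapped through the
same orientation and expressed as % from the tip, for comparison with
half the boundary (the apical compartment's midpoint).

Because no public imaging data exist for this system, the package ships a
first-class synthetic generator (`zygopolar.synthetic_data`) that renders
elongating, rotated, noisy capsule-shaped cells with planted axial
densities and a known boundary fraction, so every stage is testable
against ground truth.

## Worked example

```
$ python examples/03_compartmentalization.py
feature matrix: 110 positions x 120 features
boundary: position 48 -> 43.6% from tip (planted 43.6%)
positions disagreeing with a clean two-segment split: 0
...
$ python examples/05_division_plane.py
division planes measured: n = 12
position from tip: 22.5% +/- 1.49% (mean +/- SD)
compartment boundary: 43.6% from tip
half of apical compartment: 21.8%
difference (plane mean - half boundary): +0.6 points
```

The first run recovers the planted compartment boundary (48th of 110
positions = 43.6% from the tip) from a full synthetic study with 10%
noise and random cell orientations; the second shows that the planted
division planes cluster at the midpoint of the apical compartment.
`examples/04_classification_importance.py` prints the out-of-bag
confusion matrix (error 0.9% on this seed) and the per-structure Gini
importance ranking, with the vacuole-like probe first.

A thin CLI wraps the same library calls:
`zygopolar simulate`, `frames`, `orient`, `profile`, `cluster`,
`classify`, `divplane`, and `run-all` (see `zygopolar --help`).

## Layout

- `src/zygopolar/` — library (`stack_io`, `temporal`, `geometry`,
  `profile`, `compartment`, `classify`, `division`, `synthetic_data`,
  `pipeline`, `viz`, `cli`)
- `examples/` — one narrative script per capability
- `tests/` — pytest suite with independent oracles (exhaustive
  Lance–Williams Ward reference, brute-force split search, statsmodels
  Tukey reference)
- `docs/methods.md` — model, parameter, and design notes
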