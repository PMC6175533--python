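# Methods

This note documents the models and procedures implemented in `vesisort`,
the parameter choices that matter, and what the synthetic phantoms do and
do not demonstrate.

## Segmentation (vesicle registration)

The registration workflow assumes vesicles are compact, roughly spherical,
membrane-stained bodies that are darker than the surrounding cytoplasm in
stored intensity (the conventional EM display polarity: low = electron
dense).

Stages, in order:

1. **Rescaling.** Each x/y slice is resampled by bilinear interpolation to
   a 1 nm/pixel grid (`px_size_nm` is the input pixel size in nm/pixel;
   the new slice size is the old size × `px_size_nm`, rounded half to
   even). z is never resampled — slice spacing is kept as the physical
   voxel depth, so no interpolated slices are fabricated.
2. **Contrast stretching** maps the volume's min/max onto the working
   range [0, 255]; a zero-variance volume passes through unchanged.
3. **Denoising.** A per-slice mean filter with a circular kernel of
   radius 3.45 px, followed by a per-slice edge-preserving bilateral
   filter (spatial σ 3 px, range σ 10 % of the working range; both
   config-exposed — the bilateral parameters are our defaults, not
   literature values).
4. **Foreground separation.** Every slice is thresholded at its own mean
   gray value; foreground is the dark side (strictly below the mean, so a
   constant slice yields no foreground). Holes — the bright lumina
   enclosed by dark membranes — are filled per slice. A single 6-connected
   binary opening then removes specks and thin noise bridges between
   particles ("removal of interfering components"); for the compact
   vesicle bodies it is shape-preserving. Without it, pixel noise welds
   round blobs onto vesicles and drags them past the shape filter.
5. **Watershed splitting.** First a per-slice 2D watershed (seeded from
   local maxima of the slice distance transform) draws separating lines
   between touching cross-sections; then the 3D Euclidean distance map of
   the split mask (computed with the physical anisotropic spacing),
   smoothed with a 3D Gaussian of σ 3.45 voxels, seeds the final 3D
   watershed (26-connectivity). Seeding and flooding are deterministic.
6. **Particle filter.** Particles are removed, in this order of checks, if
   their volume falls outside [300, 60 000] nm³, their sphericity
   π^(1/3)·(6V)^(2/3)/A is below 0.65, or the symmetric-difference
   fraction against their moment-fitted ellipsoid exceeds 0.3. V comes
   from voxel counting and A from a marching-cubes mesh (voxel-face
   counting is only the fallback for unmeshable specks: face area
   overestimates curved surfaces by ~50 % and would misrate spheres).
   All thresholds are provisional working defaults and config-exposed.
   The sphericity default of 0.65 was chosen from measured values on
   digitized shapes: spheres of 5–15 voxel radius measure ≈ 0.91–0.93,
   while a 3×3×40 rod measures ≈ 0.55, so 0.65 cleanly separates the
   shapes the filter is meant to distinguish.

Survivors are relabeled consecutively, and each removal is reported with
the first criterion it failed.

## Features

* **Inner radius r** — the vesicle mask is eroded by the membrane
  thickness (default 4.5 nm, consistent with the 9 nm total membrane
  contribution to the outer diameter, 4.5 nm per side) and r is the mean
  Euclidean distance (in nm, honoring anisotropic spacing) from the inner
  region's centroid to its surface voxels (6-connectivity surface).
  Because the Euclidean distance transform measures center-to-center
  distances, half a voxel is subtracted before thresholding at the
  membrane thickness; without this the erosion is systematically half a
  voxel too shallow and the measured radius carries a ≈ +1 nm bias
  against planted phantom truth. If erosion would empty a region, the
  full mask is used and the record flagged.
* **Mean gray value gv** — mean stored intensity over the eroded 3D
  interior, reported in *density orientation* (electron-dense =
  numerically larger). Conventionally stored dark-low volumes are
  inverted at feature time (`gv_polarity="dark_low"`, gv = 255 − mean on
  the stretched working range); volumes already density-oriented pass
  through (`"density"`).
* **GVSD** — the sample standard deviation (ddof = 1) of gray values over
  the vesicle's full, membrane-*included* footprint on the z-slice through
  its centroid, computed on a Gaussian-blurred copy of the volume. The
  blur exists to keep the dark membrane ring contributing while
  suppressing voxel noise; its σ therefore defaults to 1.5 voxels, one
  third of the membrane thickness on the 1 nm grid. A σ comparable to the
  membrane thickness (e.g. the 3.45 used elsewhere in the workflow) blurs
  the ring away entirely and empirically *inverts* the expected class
  ordering on phantoms (CCV GVSD 22 < DCV 39 at σ 3.45 versus
  CCV 54 > DCV 36 at σ 1.5). Footprints under 2 voxels give GVSD 0.
* **distAZ** — 3D Euclidean distance in nm from the vesicle centroid
  (intensity-unweighted, full mask) to the user-supplied active-zone
  point. Voxel index i maps to coordinate i × spacing.
* **Per-tomogram normalization** — gv and distAZ are min-max normalized
  within each tomogram (min → 0, max → 1) before pooling across
  tomograms, averaging out brightness and cell-size variation; a
  degenerate tomogram (max = min) maps to all zeros with a warning.
* **gv offset** — optionally, if the darkest (highest-gv) vesicle of a
  table falls short of a reference threshold, all gv values are shifted by
  the constant that puts it there. This compensates global brightness
  drift between tomograms before standardization. No threshold is set by
  default; the value is configuration.

## Classification

The shipped classifier is a linear SVM exported as plain numbers: feature
order (r, gv, distAZ, GVSD), standardization means
μ = (10.4, 129.1, 259.1, 5.9) and SDs σ = (3.1, 4.7, 118.5, 1.7), weights
w = (−1.69, 1.65, −0.76, 1.21) and hyperplane constant b = −4.36. The
margin of a standardized vector z is m = w·z − b (so m = w·z + 4.36);
m > 0 is CCV, m < 0 is DCV, and the tie m = 0 goes to CCV, the ~9:1
majority class. The all-means vector scores exactly m = 4.36.

Two conventions deserve emphasis:

* **Intercept.** The decision rule is sometimes quoted without an
  intercept (w·x > 0); the printed hyperplane, however, sits at
  w·z = −4.36. We fold the constant into the margin, which reproduces the
  printed arithmetic exactly.
* **gv weight sign.** Retraining a linear SVM on density-oriented
  synthetic features always yields a *negative* gv weight (denser →
  DCV), whereas the shipped model carries +1.65 — consistent with its
  training features having been brightness-oriented (darker = lower gv).
  The shipped parameters are embedded verbatim; the `gv_polarity` flag
  controls the feature-side orientation, and for quantitative work on new
  data a retrained model (whose signs match its own feature convention by
  construction) is recommended. The pre-trained model's accuracy is only
  meaningful on data resembling its original training distribution, which
  the phantoms deliberately do not replicate.

Numeric label codes differ by context and are applied only at
serialization boundaries: training files use CCV = +1 / DCV = −1; the
result log uses CCV = 1 / DCV = 0. Internally classes are the symbolic
pair {CCV, DCV}.

## Training and evaluation

Label encoding: D → −1, E (error/non-assignable) rows are dropped, C and
N (non-determinable, shown to behave like CCVs) → +1. Training
standardizes with the training data's mean and sample SD and delegates the
numerical fit to scikit-learn: linear SVM (C = 1), RBF SVM, random forest
(10 or 1500 bootstrap trees, probability-weighted voting) or KNN (k = 10,
uniform weights, Euclidean metric). A trained linear SVM is exportable as
the plain-number classifier above; an equivalence test pins the exported
model's predictions to the trainer's.

Cross-validation is leave-one-file-out: one fold per source table, with
standardization computed on the training folds only. Metrics are
DCV-positive: precision = tp/(tp+fp), recall = tp/(tp+fn),
F = 2PR/(P+R), plus overall accuracy. A fold without DCVs has undefined
precision/recall/F; such folds are excluded from that metric's mean ± SD
(sample SD, ddof = 1) rather than coerced to 0 or 1, which would bias the
summary systematically.

## Pool statistics

* DCV ratio: 100·n_DCV/n_total, rounded half away from zero to the
  requested precision (whole percent for count tables, one decimal for
  small fractions).
* Diameter conversion: inner diameter = 2r; estimated outer diameter =
  2r + 9 nm. The estimate is approximate and not directly comparable to
  manual caliper measurements.
* Mann-Whitney U, two-sided, with U computed by pairwise counting (ties
  count ½). For groups of ≤ 8 each the p value is exact by exhaustive
  enumeration of all group assignments (valid under ties); larger samples
  use the tie-corrected normal approximation with continuity correction.
  No multiple-testing correction by default (optional Bonferroni flag).
* Distance distributions: empirical CDF plus a Gaussian KDE whose
  bandwidth is 0.07 × the sample maximum (the kernel family is our
  choice; the bandwidth rule is fixed).
* Cell-size change: |Δx| + |Δy| of the first- versus last-slice extents.
* Cell volume: per-slice outline polygon areas (shoelace, via shapely)
  × z spacing.

## Phantoms

`generate_phantom_stack` renders spherical vesicles into a uniform
background: every vesicle carries a dark membrane shell (4.5 nm); CCVs
enclose a lumen near the background level, DCVs a dense dark interior.
DCVs are drawn larger (inner radius 15.5 ± 2.0 nm vs 9.8 ± 1.5 nm) and
their centers are rejection-sampled with acceptance ∝ (d/d_max)^bias
toward larger active-zone distances, reproducing the reported pool
geometry (DCVs at the rim, CCVs clustered at the release site). Roughly
one vesicle in eight is a DCV by default. Placement is non-overlapping by
rejection sampling; impossible requests raise a capacity error. Additive
Gaussian pixel noise and an optional mild z blur (a stand-in for
tomographic elongation) complete the render. The default grid is
1 × 1 × 1.2 nm, z coarser than x/y.

`sample_feature_table` skips imaging entirely and draws the four features
from class-conditional Gaussians whose locations mirror the reported group
contrasts (CCV r ≈ 9.8 vs DCV ≈ 15.5 nm; DCVs denser in gv, lower in
GVSD, further in distAZ). These tables drive the training/evaluation
tests at realistic class imbalance (12 % DCV).

What the phantoms do **not** model: the missing wedge and reconstruction
artifacts, membrane deformation or non-spherical vesicles, cytoplasmic
clutter (ribosomes, filaments, dense projections) and spatially
correlated noise. Passing phantom tests therefore demonstrates the
correctness and determinism of the algorithms and their behavior under
idealized contrast — not segmentation performance on real tomograms,
where the particle-filter thresholds and denoising parameters will need
tuning.

## Problem sizes and accuracy of the acceptance computations

The acceptance script uses 20-vesicle phantoms on a 48 × 220 × 220 voxel
grid (≈ 58 × 220 × 220 nm) and 15 synthetic feature tables of 130
vesicles each — large enough for stable statistics while keeping a full
run in the minutes range on one CPU. On the noiseless phantom all 20
vesicles are recovered with sub-voxel median center error; the
pool-median absolute radius error is ≈ 0.5 nm. Per-vesicle radius errors
scatter by about ±1 voxel from digitization of the sphere surface and of
the threshold boundary, so the median across the pool — not the worst
single vesicle — is the reported accuracy measure. With pixel noise at
10 % of the membrane-to-background contrast, detection recall stays at or
above 80 %, at the cost of some spurious round noise blobs passing the
shape filter (recall, not precision, is the acceptance quantity there).

## Known limitations

* The MRC reader/writer covers the plain MRC2014 dialect (modes 0/1/2/6,
  no extended headers written); cell dimensions are interpreted in nm.
* The 2D watershed split can over-segment very non-convex cross-sections;
  vesicles are convex, so this does not arise in practice.
* The gv-offset comparison direction follows one consistent reading of
  the macro's description (shift up when the darkest vesicle is too
  light); the reference threshold is configuration with no default.
* Exact Mann-Whitney enumeration is limited to groups of ≤ 8 (12 870
  assignments at 8 + 8); beyond that the asymptotic approximation is
  standard practice.
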