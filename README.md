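# vesisort

Automated classification of synaptic vesicles in 3D electron tomograms.

Presynaptic boutons contain two morphologically distinct vesicle pools:
abundant small **clear-core vesicles** (CCVs, classical neurotransmitters)
and rarer, larger **dense-core vesicles** (DCVs, neuropeptides and
active-zone cargo). Counting and comparing these pools across conditions —
for example between *C. elegans* young adult hermaphrodites and dauer
larvae — requires classifying hundreds of vesicles per tomogram, which is
slow and error-prone by hand. `vesisort` automates the whole chain for
anyone quantifying vesicle pools in electron tomograms:

1. **Segmentation** — vesicles are registered in the raw tomogram by
   rescaling to a 1 nm/pixel grid, contrast stretching, mean + bilateral
   denoising, per-slice mean-brightness thresholding with hole filling,
   a 2D-then-3D watershed on a Gaussian-smoothed distance map, and a
   particle filter on volume, sphericity and ellipsoid fit.
2. **Feature readout** — four features per vesicle: inner radius *r* (mean
   centroid-to-surface distance after eroding the 4.5 nm membrane), mean
   gray value *gv* of the membrane-excluded interior (density-oriented:
   electron-dense = larger), the gray-value standard deviation *GVSD* on
   the vesicle's central slice (a membrane/lumen contrast proxy), and the
   3D Euclidean distance *distAZ* to the annotated active-zone point.
3. **Classification** — a standardized linear decision rule. With
   z = (x − μ)/σ per feature, the shipped pre-trained model assigns CCV
   when

       m = −1.69·z_r + 1.65·z_gv − 0.76·z_distAZ + 1.21·z_GVSD + 4.36 > 0

   and DCV otherwise (μ, σ and the weights ship with the package; any
   linear SVM retrained with `vesisort.train` exports the same form).
4. **Evaluation and statistics** — leave-one-file-out cross-validation
   with DCV-specific precision/recall/F-score, vesicle-pool ratios, the
   inner-radius → outer-diameter conversion (2r + 9 nm), Mann-Whitney U
   group comparisons, and distance distributions (empirical CDF plus a
   Gaussian KDE with bandwidth = 0.07 × data maximum).

A phantom generator renders synthetic bouton tomograms (membrane-bound
spherical vesicles, DCVs biased away from the active zone, Gaussian noise)
with exact ground truth, so the full pipeline is testable without any
microscope data.

## Worked example

```python
import vesisort as vs
from vesisort.phantom import PhantomSpec, generate_phantom_stack

spec = PhantomSpec(n_vesicles=20, dcv_fraction=0.15, seed=1)
stack, truth = generate_phantom_stack(spec)

labels, scaled = vs.segment(stack, px_size_nm=1.0)
table = vs.extract_feature_table(scaled, labels, spec.az_point_nm,
                                 gv_polarity="dark_low")
print(len(table), "vesicles;",
      "median r = %.1f nm" % table["r"].median())
inner, outer = vs.diameter_conversion(table["r"].median())
print("estimated outer diameter = %.1f nm" % outer)
```

prints

```
20 vesicles; median r = 10.2 nm
estimated outer diameter = 29.4 nm
```

— all 20 planted vesicles are recovered, and the median inner radius of
10.2 nm (the phantom plants CCV radii around 9.8 nm plus a small
digitization bias) converts to an estimated outer diameter of
2r + 9 = 29.4 nm. Applying a retrained linear model then labels each
vesicle CCV/DCV and `vesisort.summarize_groups` compares the pools.

The same pipeline is available from the shell:

```sh
vesisort simulate --seed 1 --out stack.tif --truth truth.csv
vesisort segment --in stack.tif --px-size-nm 1.0 --out labels.tif --scaled scaled.tif
vesisort features --stack scaled.tif --labels labels.tif --az 110,0,28.8 --out features.csv
vesisort classify --features features.csv --out classified.csv --log result.log
vesisort crossval --features a.csv --features b.csv --features c.csv --report report.json
```

## Documentation

`docs/methods.md` describes the models, parameter choices, numerical
details and known limitations.
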