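# Methods

`canopytex` implements a texture-based pipeline for estimating crop
aboveground biomass (AGB, kg/ha) from multispectral canopy imagery, and a
synthetic-scene generator that makes the whole pipeline testable without
field data.  This note documents the models, the defaults and the design
choices that were genuinely open.

## Pipeline model

The analysis chain is:

1. **Radiometric calibration (empirical line method).**  Per band,
   reflectance `R = DN * gain + offset`, with `(gain, offset)` fitted by
   ordinary least squares on diffuse calibration panels of known
   reflectance.  Fits are per-band and independent; calibrated
   reflectance is clipped to [0, 1] by default (the number of clipped
   pixels is logged), since the downstream quantization assumes bounded
   input.

2. **PCA band compression.**  The five bands (blue, green, red, red
   edge, near infrared) are z-scored over in-plot pixels and compressed
   with PCA; the leading components whose cumulative explained-variance
   ratio *strictly exceeds* 90% are retained.  On the default scenes
   this is always two components: PC1 is dominated by the
   canopy-background contrast, PC2 by background brightness and edge
   structure.  Standardization is deliberate — the NIR band's dynamic
   range would otherwise dominate the decomposition.  PCA is fitted per
   stage, since band statistics shift as the canopy develops.

3. **Sliding-window GLCM texture.**  Each selected component image is
   linearly quantized into `Ng = 32` grey levels using its global
   min-max range (global, not per-window, so texture values are
   comparable across the scene).  For every pixel, the grey-level
   co-occurrence matrix (GLCM) of its centred window is accumulated at
   displacement 1 and one of four directions — 0° along the planting
   rows (D1), 45° (D2), 90° (D3), 135° (D4), counter-clockwise in image
   coordinates — and eight statistics are evaluated: Mean, Var, Hom,
   Con, Dis, Ent, SM, Cor.  The GLCM is symmetric (each pair counted in
   both orders), making θ and θ+180° equivalent.  Entropy uses the
   natural logarithm.  The non-directional (ND) raster is the pixel-wise
   mean of the four directional rasters.  Windows are 3×3, 7×7 and 13×13
   (S/M/L); edges are handled by reflect-padding, and plot buffers keep
   the analysis away from the pads.  The full grid is
   2 components × 8 features × 3 windows × 5 directions = 240 rasters.

   Numerical conventions: `Cor` is the Haralick correlation
   `(Σ i·j·P(i,j) − μ_i μ_j)/(σ_i σ_j)` and is defined as 0 for
   constant windows (σ = 0), i.e. "no linear-dependency signal";
   `Mean`/`Var` are the marginal moments `μ_i`, `σ_i²` (for a symmetric
   GLCM the two marginals coincide, so the single-μ notation is
   well-defined); `0·log 0 ≡ 0` in the entropy.  A constant image
   quantizes to all-zeros rather than erroring.

   The per-pixel engine is a numba kernel that recomputes each window
   histogram from scratch, tracking touched bins so cost scales with
   window pair count.  Because the pair total T is the same for every
   interior window of a cell, entropy reduces to
   `ln T − (1/T) Σ cnt·ln cnt` with a precomputed `c·ln c` table, and
   all other sums accumulate in integers.  A full 240-raster stack on a
   ~620×1050-px scene takes ~25 s on one CPU.

4. **Plot-level modeling.**  Features are plot means over plot
   footprints shrunk by a 6-px buffer (edge rows grow atypically and
   would bias plot statistics).  Samples are split 70/30
   stratified by growth stage (largest-remainder allocation; the
   calibration size is `round(0.7 n)` with ties toward calibration); the
   random-forest `mtry` is tuned by k-fold cross-validation on the
   calibration set (highest mean CV R², ties to lowest RMSE, then
   smallest `mtry`), and the forest (default `ntree = 1000`) is
   evaluated with R² (squared Pearson correlation between observed and
   estimated AGB), RMSE (kg/ha) and rRMSE (100·RMSE/mean observed, %).
   Importance is permutation %IncMSE: each predictor column is permuted
   several times on a held-out set and the mean increase in MSE is
   expressed as a percentage of the unpermuted model MSE.  The default
   fold count is 5 (3 in the scaled-down runs below); the exact CV
   scheme was an open choice and 5-fold is the standard small-n default.

5. **Sweeps.**  For every (stage, window, direction) cell — and pooled
   across stages — a model is trained on *that cell's* 16 predictors
   (8 features × 2 components); the sweep table mirrors the
   window/direction sensitivity tables of UAV texture studies.  Per-cell
   modeling (rather than feeding all 240 features to every cell) is the
   only reading under which one accuracy per cell is meaningful.  One
   master seed expands into per-cell seeds through a CRC32 hash of the
   cell key, so cells are independent but the sweep is reproducible.
   The spectral baseline uses the five per-plot mean band reflectances
   under the identical protocol.

## The synthetic campaign

The generator emulates a rice nitrogen trial: 4 N levels × 3 varieties
× 3 replicates = 36 plots of 2 m × 8 m at 1.7 cm ground sampling
distance, imaged at four stages — late tillering (LT), booting (B),
heading-to-flowering (HtF), early filling (EF).  Default plots are
64×256 px (a ~620×1050-px scene) rather than the full ~118×470 px per
plot, so a full season renders in seconds and a full texture stack in
tens of seconds; full size is a parameter.

**Canopy.**  Plants are soft-edged discs on the 30 cm × 15 cm
row/plant lattice (rows parallel to the image row axis), with per-plant
radius and brightness jitter.  The base disc radius is bisected per plot
so realized cover matches the plot's target cover (within ±0.05 over
covers 0.1–0.9).  Target cover = stage cover × an N-level multiplier
(N0 0.75 … N3 1.15) × a small lognormal-style jitter; stage covers rise
0.35 → 0.65 → 0.80 → 0.90 (LT→EF).  A multiplicative leaf-scale texture
(σ≈1 px) sits on canopy pixels; its amplitude grows with canopy density
(leaf layering and internal shadowing) until cover ≈ 0.65, and after
heading its per-plot amplitude also varies randomly (panicle mottling
state), independently of treatment.

**Background.**  A two-phase soil/water mixture: smooth blobs (σ = 8 px)
thresholded at the stage water fraction (0.50 → 0.20 across the season,
the paddy drying out), with the water phase rendered as a darker version
of the soil spectrum.  Keeping the two phases spectrally proportional is
a deliberate simplification: it keeps the five-band manifold
two-dimensional (canopy contrast + background brightness), which is how
real paddy scenes compress into two >90% principal components.  On top
sit a smooth brightness field, pixel-rough speckle (glint/clods) whose
amplitude is strongest early (0.35 at LT, 0.06 at EF) and varies
per plot with the local drying/glinting state, and a per-plot water
fraction jitter (sd 0.15) — paddy water depth is uneven.  These
per-plot background states are the "background noise" that penalizes
texture windows large enough to mix background into every window.

**AGB.**  Per-plot AGB = N-level stage mean × lognormal noise with a
stage coefficient of variation (0.18 → 0.12).  The underlying normal
draw is shared with the plot's cover jitter, coupling biomass to canopy
cover at replicate level (rank correlation > 0.5 within every stage by
construction — this is the signal the downstream model must recover; it
comes out ≈ 1.0 at early stages).  Stage means run ≈ 1.9 t/ha (LT) to
≈ 11.2 t/ha (EF) with a between-N-level CV ≈ 0.5, matching the
magnitude and spread a fertilizer-gradient rice trial shows.
With `agb_cv = 0` all replicates of an (N level, stage) cell are
identical.

**Sensor.**  Independent Gaussian noise of sd 0.005 reflectance per
band, clipped to [0, 1] — sub-percent radiometric noise typical of a
calibrated reflectance product.

**What the generator does not emulate.**  No BRDF or sun-sensor
geometry (so the D2/D4 asymmetry real campaigns show from backscatter
has no counterpart here), no weeds, no lodging, no geometric or
co-registration error, no spectral-response differences between bands
beyond the fixed end-member spectra.  Passing tests therefore show the
pipeline recovers the kinds of structure the generator encodes —
cover-coupled biomass, stage-dependent background interference — not
that it reproduces any real campaign's accuracy values.

## Expected qualitative behaviour

Two stochastic properties of the generator/model pair are asserted by
the test suite at desk scale:

* **Signal recovery.**  On the default seeded season, a pooled
  random-forest model on all 240 texture features reaches validation
  R² ≥ 0.6 (measured ≈ 0.93–0.97), and the informative features outrank
  appended pure-noise features in at least 9 of 10 seeded runs.
* **Window-size effect.**  On scaled-down scenes (32×128-px plots,
  windows S and L, ND direction, 5 seeded replicates), the small window
  matches or beats the large one at the lowest-coverage stage in a
  majority of replicates, and the reverse holds at the highest-coverage
  stage.  Mechanistically: early in the season, small windows act as
  local phase classifiers whose plot means depend only on cover, while
  large windows mix background pairs into every window and inherit the
  per-plot background state (water fraction, speckle amplitude) as
  noise; late in the season the background is nearly invisible, the
  canopy's fine-scale state varies per plot (panicle mottling), and the
  large window's macro gap structure is the cleaner signal.

## Scaled-down problem sizes

The library defaults follow the full protocol (`ntree = 1000`,
15-candidate mtry grid, 5-fold CV).  The test suite and the acceptance
script run the same code with 300 trees, coarse mtry grids (3–4
candidates) and 3-fold CV, and the replicate comparison uses 32×128-px
plots; these choices change the reported metrics by far less than
seed-to-seed spread and keep a full run in minutes on one CPU.  All
randomness flows from explicit seeds; scenes, splits, forests and
sweeps are bit-reproducible under a fixed seed.

## Known limitations

* The GLCM engine supports arbitrary odd windows and displacements, but
  only displacement 1 is exercised by tests and defaults.
* Quantization uses the global image range; a contamination of the
  range (a single extreme pixel) compresses the remaining levels.
* %IncMSE is computed by permutation on a held-out set rather than the
  per-tree out-of-bag variant of classical random-forest packages; the
  ranking agrees but absolute percentages are not interchangeable.
* Raster I/O is plain multi-page TIFF with a JSON description tag; no
  CRS/geotransform handling.
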