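# canopytex

Texture-based estimation of crop aboveground biomass (AGB) from
multispectral canopy imagery — and a synthetic row-crop scene generator
that makes the whole pipeline reproducible on a laptop.

UAV multispectral surveys of row crops (the motivating case is a rice
nitrogen trial: 4 N levels × 3 varieties × 3 replicates = 36 plots,
imaged at four growth stages) estimate plot biomass from canopy
reflectance.  Spectral means saturate as the canopy closes and are
noisy over early-season water/soil background; grey-level co-occurrence
matrix (GLCM) texture features complement them — but they depend
strongly on the moving-window size and direction used to compute them.
`canopytex` implements the full analysis needed to study that
sensitivity:

* **empirical line calibration** — per band, `R_i = DN_i·gain_i + offset_i`
  fitted by OLS on reflectance panels;
* **PCA band compression** — standardized bands, components kept while
  the cumulative explained variance ratio exceeds 90% (two on these
  scenes);
* **a from-scratch sliding-window GLCM engine** (numba) computing the
  eight Haralick statistics

  Mean, Var, Hom = ΣP(i,j)/(1+(i−j)²), Con = Σ(i−j)²P(i,j),
  Dis = Σ|i−j|P(i,j), Ent = −ΣP·lnP, SM = ΣP², Cor = (Σij·P − μ_iμ_j)/(σ_iσ_j)

  over windows 3/7/13 px (S/M/L) and directions 0°/45°/90°/135°
  (D1–D4) plus their non-directional average (ND), at displacement 1
  and Ng = 32 grey levels — 2 × 8 × 3 × 5 = 240 texture rasters per
  scene;
* **plot-level random-forest regression** — stratified 70/30 split,
  CV-tuned `mtry`, `ntree = 1000`, metrics R² (squared Pearson), RMSE
  and rRMSE = 100·RMSE/mean(AGB), permutation %IncMSE importance;
* **sweep orchestration** producing per-(stage, window, direction)
  accuracy tables, a spectral (band-mean) baseline, importance reports
  and per-plot AGB maps;
* **a synthetic campaign generator**: plants on the 30 cm × 15 cm
  row/plant lattice over a drying soil/water background, stage-dependent
  canopy cover, and plot AGB (1.9–11.2 t/ha across stages) coupled to
  canopy cover so the texture features carry a recoverable signal.

## Worked example

```python
from canopytex import (
    GLCMGrid, RFConfig, generate_season, pca_compress, build_full_stack,
)
from canopytex.evaluation import run_sweep, best_cell

season = generate_season(seed=42)          # 36 plots x 4 stages
print(f"{len(season.design.plots)} plots, {len(season.agb)} AGB samples")

scene = season.scenes["B"]                 # booting-stage reflectance
pca = pca_compress(scene, mask=season.design.plot_mask())
print("explained variance:",
      [round(float(v), 3) for v in pca.explained_variance_ratio],
      "-> components kept:", pca.n_selected)

stack = build_full_stack(pca)
print(f"{len(stack)} texture rasters, e.g. {sorted(stack)[0]}")

sweep = run_sweep(
    {"B": scene}, season.agb[season.agb.stage == "B"], season.design,
    GLCMGrid(windows=(3, 13), directions=("D2",), include_nd=False),
    RFConfig(ntree=300, mtry_grid=(2, 4, 8), cv_folds=3, seed=42),
    include_pooled=False,
)
print(sweep.table[["stage", "window", "direction", "val_r2",
                   "val_rmse", "val_rrmse"]].round(3).to_string(index=False))
print("best cell at booting:", *best_cell(sweep, "B"))
```

prints

```
36 plots, 144 AGB samples
explained variance: [0.518, 0.465, 0.011, 0.006, 0.0] -> components kept: 2
240 texture rasters, e.g. PC1_Con_L_D1
stage window direction  val_r2  val_rmse  val_rrmse
    B      S        D2   0.944  1125.882     14.984
    B      L        D2   0.876  1851.774     18.173
best cell at booting: S D2
```

Reading: at booting-stage canopy cover, texture from the small 3×3
window predicts held-out plot AGB with R² 0.94 and an error of ~15% of
the mean (1126 kg/ha); the 13×13 window mixes in more background and
does worse — the window-size sensitivity the package exists to study.

A `canopytex` console script wraps the same steps
(`simulate`, `calibrate`, `texture`, `sweep`, `baseline`); all commands
take explicit `--seed` and write TIFF/CSV/JSON artifacts.

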