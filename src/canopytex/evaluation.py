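"""Window x direction sweep orchestration and comparison tables.

Reproduces the experiment structure of a texture-parameter sensitivity
study: for every growth stage (and the pooled season), for every window
size (S/M/L) and direction (D1..D4, ND), a random-forest AGB model is
trained on that cell's texture features alone and its accuracy recorded;
a spectral baseline (per-plot mean band reflectance) is fitted with the
same protocol for comparison, and permutation-importance rankings are
summarized per cell.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .modeling import (
    ModelResult,
    ModelingError,
    RFConfig,
    assemble_feature_table,
    derive_seed,
    extract_plot_features,
    fit_and_evaluate,
    run_protocol,
    split_samples,
)
from .scene import MultispectralScene
from .synthetic import FieldDesign
from .texture import GLCMGrid, TextureStack, build_full_stack, pca_compress, window_label

log = logging.getLogger(__name__)

POOLED = "All"

SWEEP_COLUMNS = [
    "stage",
    "window",
    "direction",
    "cal_r2",
    "cal_rmse",
    "cal_rrmse",
    "val_r2",
    "val_rmse",
    "val_rrmse",
    "mtry",
    "n_cal",
    "n_val",
    "seed",
]


class EvaluationError(ValueError):
    """Invalid sweep input or scope."""


@dataclass
class SweepResult:
    """All (stage, window, direction) model metrics of one sweep."""

    table: pd.DataFrame
    models: dict[tuple[str, str, str], ModelResult] = field(default_factory=dict)

    def rows(self, scope: str) -> pd.DataFrame:
        sel = self.table[self.table["stage"] == scope]
        if sel.empty:
            raise EvaluationError(f"no sweep rows for scope {scope!r}")
        return sel


def stage_feature_tables(
    scenes_by_stage: dict[str, MultispectralScene],
    agb_table: pd.DataFrame,
    design: FieldDesign,
    grid: GLCMGrid = GLCMGrid(),
    pca_threshold: float = 0.90,
) -> tuple[dict[str, pd.DataFrame], dict[str, int]]:
    """Per-stage full texture feature tables (all sweep cells as columns).

    PCA is fitted per stage on in-plot pixels; the full texture stack is
    built once per stage and reduced to per-plot means, so each sweep
    cell later just selects its own column subset.  Returns the tables
    and the per-stage count of selected PCA components.
    """
    mask = design.plot_mask()
    tables: dict[str, pd.DataFrame] = {}
    n_components: dict[str, int] = {}
    for stage, scene in scenes_by_stage.items():
        pca = pca_compress(scene, mask=mask, threshold=pca_threshold)
        stack = build_full_stack(pca, grid)
        features = extract_plot_features(stack, design)
        agb_stage = agb_table[agb_table["stage"] == stage]
        if agb_stage.empty:
            raise EvaluationError(f"no AGB rows for stage {stage!r}")
        tables[stage] = assemble_feature_table(features, agb_stage, design)
        n_components[stage] = pca.n_selected
        log.info(
            "stage %s: %d PCA components, %d texture rasters",
            stage,
            pca.n_selected,
            len(stack),
        )
    return tables, n_components


def cell_feature_columns(
    table: pd.DataFrame, window_px: int, direction: str
) -> list[str]:
    """The feature columns of one (window, direction) sweep cell."""
    suffix = f"_{window_label(window_px)}_{direction}"
    cols = [c for c in table.columns if c.startswith("PC") and c.endswith(suffix)]
    if not cols:
        raise EvaluationError(
            f"no feature columns for window {window_px}, direction {direction}"
        )
    return cols


def run_sweep(
    scenes_by_stage: dict[str, MultispectralScene],
    agb_table: pd.DataFrame,
    design: FieldDesign,
    grid: GLCMGrid = GLCMGrid(),
    rf_config: RFConfig = RFConfig(),
    keep_models: bool = False,
    include_pooled: bool = True,
) -> SweepResult:
    """Model every (stage, window, direction) cell plus pooled-season rows.

    Each cell's model uses only that cell's features across the selected
    PCA components (8 features x n_components predictors).  Each cell
    gets a deterministic sub-seed derived from the master seed and the
    cell key, so cells are independent but the sweep is reproducible.
    """
    tables, _ = stage_feature_tables(
        scenes_by_stage, agb_table, design, grid
    )
    return run_sweep_from_tables(
        tables, grid, rf_config, keep_models=keep_models,
        include_pooled=include_pooled,
    )


def run_sweep_from_tables(
    tables: dict[str, pd.DataFrame],
    grid: GLCMGrid = GLCMGrid(),
    rf_config: RFConfig = RFConfig(),
    keep_models: bool = False,
    include_pooled: bool = True,
) -> SweepResult:
    """Sweep over precomputed per-stage feature tables.

    Same protocol as :func:`run_sweep` but skips scene-level texture
    extraction; useful when the full feature tables already exist.
    """
    pooled = pd.concat(tables.values(), ignore_index=True)

    scopes: list[tuple[str, pd.DataFrame]] = list(tables.items())
    if include_pooled:
        scopes.append((POOLED, pooled))

    rows = []
    models: dict[tuple[str, str, str], ModelResult] = {}
    for scope, table in scopes:
        for window_px in grid.windows:
            for direction in grid.direction_labels:
                cols = cell_feature_columns(table, window_px, direction)
                seed = derive_seed(rf_config.seed, scope, window_px, direction)
                cell_config = RFConfig(
                    ntree=rf_config.ntree,
                    mtry_grid=rf_config.mtry_grid,
                    split_fraction=rf_config.split_fraction,
                    cv_folds=rf_config.cv_folds,
                    seed=seed,
                    importance_repeats=rf_config.importance_repeats,
                )
                try:
                    cal, val = split_samples(
                        table, cell_config.split_fraction, seed
                    )
                    result = fit_and_evaluate(cal, val, cell_config, cols)
                except ModelingError as exc:  # partial results with markers
                    log.warning(
                        "sweep cell (%s, %s, %s) failed: %s",
                        scope,
                        window_px,
                        direction,
                        exc,
                    )
                    rows.append(
                        {
                            "stage": scope,
                            "window": window_label(window_px),
                            "direction": direction,
                            "seed": seed,
                            "error": str(exc),
                        }
                    )
                    continue
                rows.append(
                    {
                        "stage": scope,
                        "window": window_label(window_px),
                        "direction": direction,
                        "cal_r2": result.calibration["r2"],
                        "cal_rmse": result.calibration["rmse"],
                        "cal_rrmse": result.calibration["rrmse"],
                        "val_r2": result.validation["r2"],
                        "val_rmse": result.validation["rmse"],
                        "val_rrmse": result.validation["rrmse"],
                        "mtry": result.mtry,
                        "n_cal": len(cal),
                        "n_val": len(val),
                        "seed": seed,
                    }
                )
                if keep_models:
                    models[(scope, window_label(window_px), direction)] = result
    return SweepResult(table=pd.DataFrame(rows), models=models)


def best_cell(sweep: SweepResult, scope: str) -> tuple[str, str]:
    """(window, direction) with the highest validation R^2 in a scope.

    Ties break toward the lowest validation RMSE.
    """
    rows = sweep.rows(scope).dropna(subset=["val_r2"])
    if rows.empty:
        raise EvaluationError(f"no valid rows for scope {scope!r}")
    ranked = rows.sort_values(
        ["val_r2", "val_rmse"], ascending=[False, True], kind="mergesort"
    )
    top = ranked.iloc[0]
    return str(top["window"]), str(top["direction"])


def spectral_baseline(
    reflectance_scenes: dict[str, MultispectralScene],
    agb_table: pd.DataFrame,
    design: FieldDesign,
    rf_config: RFConfig = RFConfig(),
) -> dict[str, ModelResult]:
    """Per-stage + pooled models on per-plot mean band reflectance.

    Five predictors (the band means), same split/tuning/metric protocol
    as the texture models.
    """
    tables = {}
    for stage, scene in reflectance_scenes.items():
        features = extract_plot_features(scene, design)
        agb_stage = agb_table[agb_table["stage"] == stage]
        tables[stage] = assemble_feature_table(features, agb_stage, design)
    pooled = pd.concat(tables.values(), ignore_index=True)
    tables[POOLED] = pooled

    results = {}
    for scope, table in tables.items():
        cfg = RFConfig(
            ntree=rf_config.ntree,
            mtry_grid=rf_config.mtry_grid,
            split_fraction=rf_config.split_fraction,
            cv_folds=rf_config.cv_folds,
            seed=derive_seed(rf_config.seed, "spectral", scope),
            importance_repeats=rf_config.importance_repeats,
        )
        results[scope] = run_protocol(table, cfg)
    return results


def importance_report(
    sweep: SweepResult,
    scope_direction: str = "D2",
) -> pd.DataFrame:
    """Tidy permutation-importance table for one direction's cells.

    One row per (stage, window, feature) with the %IncMSE score, the PCA
    component the feature came from, and the within-cell rank (1 = most
    important).  Requires the sweep to have been run with
    ``keep_models=True``.
    """
    if not sweep.models:
        raise EvaluationError(
            "no retained models; rerun the sweep with keep_models=True"
        )
    rows = []
    for (scope, window, direction), result in sweep.models.items():
        if direction != scope_direction:
            continue
        items = sorted(result.importance.items(), key=lambda kv: -kv[1])
        for rank, (feature, score) in enumerate(items, start=1):
            component, feat_name, win, direc = feature.split("_")
            rows.append(
                {
                    "stage": scope,
                    "window": window,
                    "direction": direc,
                    "feature": feat_name,
                    "component": component,
                    "score": score,
                    "rank": rank,
                }
            )
    if not rows:
        raise EvaluationError(
            f"no retained models for direction {scope_direction!r}"
        )
    return pd.DataFrame(rows)


def agb_map(
    result: ModelResult,
    texture_stack: TextureStack,
    design: FieldDesign,
) -> tuple[np.ndarray, pd.DataFrame]:
    """Per-plot predicted AGB painted over the plot footprints.

    Plot-level predictions come from the plot means of the model's
    features; pixels outside any plot are NaN.  Returns the raster and a
    (plot_id, agb_pred) table.
    """
    missing = [f for f in result.feature_names if f not in texture_stack]
    if missing:
        raise EvaluationError(f"texture stack missing feature(s): {missing[:5]}")
    features = extract_plot_features(
        {k: texture_stack[k] for k in result.feature_names}, design
    )
    X = features[result.feature_names].to_numpy(dtype=float)
    preds = result.model.predict(X)

    raster = np.full(design.scene_shape_px, np.nan, dtype=np.float64)
    rows = []
    for plot, pred in zip(design.plots, preds):
        r0, r1, c0, c1 = plot.pixel_region
        raster[r0:r1, c0:c1] = pred
        rows.append({"plot_id": plot.plot_id, "agb_pred": float(pred)})
    return raster, pd.DataFrame(rows)
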