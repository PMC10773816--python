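"""Plot-level feature aggregation and the random-forest AGB protocol.

The modeling protocol mirrors the common UAV phenotyping workflow:
per-plot means of feature rasters over buffered plot regions form the
sample table; a stratified 70/30 split separates calibration from
validation; mtry is tuned by k-fold cross-validation on the calibration
set; a 1000-tree random forest is fitted and evaluated with R^2 (squared
Pearson correlation), RMSE (kg/ha) and rRMSE (percent of the observed
mean); predictor importance is the permutation %IncMSE.
"""

from __future__ import annotations

import math
import warnings
import zlib
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestRegressor
from sklearn.model_selection import KFold

from .scene import MultispectralScene
from .synthetic import FieldDesign
from .texture import TextureStack

LABEL_COLUMNS = ("plot_id", "stage", "n_level", "variety", "replicate")
TARGET_COLUMN = "agb_kg_ha"


class ModelingError(ValueError):
    """Invalid modeling input."""


def derive_seed(master_seed: int, *parts) -> int:
    """Stable sub-seed (< 2**31) from a master seed and a cell key."""
    key = ":".join([str(master_seed), *map(str, parts)])
    return zlib.crc32(key.encode()) % (2**31)


# ---------------------------------------------------------------------------
# Metrics
# ---------------------------------------------------------------------------

def r2_score_pearson(obs: np.ndarray, est: np.ndarray) -> float:
    """Squared Pearson correlation between observed and estimated values."""
    obs = np.asarray(obs, dtype=float)
    est = np.asarray(est, dtype=float)
    so = obs.std()
    se = est.std()
    if so == 0:
        raise ModelingError("R^2 undefined: observed values have zero variance")
    if se == 0:
        return 0.0
    r = float(np.corrcoef(obs, est)[0, 1])
    return r * r


def rmse(obs: np.ndarray, est: np.ndarray) -> float:
    obs = np.asarray(obs, dtype=float)
    est = np.asarray(est, dtype=float)
    return float(np.sqrt(np.mean((est - obs) ** 2)))


def rrmse(obs: np.ndarray, est: np.ndarray) -> float:
    """Relative RMSE: 100 x RMSE / mean(observed), in percent."""
    mean_obs = float(np.mean(obs))
    if mean_obs == 0:
        raise ModelingError("rRMSE undefined: observed mean is zero")
    return 100.0 * rmse(obs, est) / mean_obs


def evaluation_metrics(obs: np.ndarray, est: np.ndarray) -> dict[str, float]:
    return {
        "r2": r2_score_pearson(obs, est),
        "rmse": rmse(obs, est),
        "rrmse": rrmse(obs, est),
    }


# ---------------------------------------------------------------------------
# Feature extraction
# ---------------------------------------------------------------------------

def extract_plot_features(
    source: TextureStack | dict | MultispectralScene,
    design: FieldDesign,
) -> pd.DataFrame:
    """Mean of each feature raster over every buffered plot region.

    ``source`` is either a texture stack (mapping key -> raster) or a
    reflectance scene (per-band means, columns named after the bands).
    Returns a DataFrame indexed by plot_id with one column per feature.
    """
    if isinstance(source, MultispectralScene):
        rasters = {name: source.band(name) for name in source.band_names}
    else:
        rasters = dict(source)
    if not rasters:
        raise ModelingError("no feature rasters supplied")

    shape = next(iter(rasters.values())).shape
    rows = {}
    for plot in design.plots:
        r0, r1, c0, c1 = design.buffered_region(plot)
        if not (0 <= r0 < r1 <= shape[0] and 0 <= c0 < c1 <= shape[1]):
            raise ModelingError(
                f"buffered region of plot {plot.plot_id} empty or outside raster"
            )
        rows[plot.plot_id] = {
            name: float(raster[r0:r1, c0:c1].mean())
            for name, raster in rasters.items()
        }
    out = pd.DataFrame.from_dict(rows, orient="index")
    out.index.name = "plot_id"
    return out


def assemble_feature_table(
    features: pd.DataFrame,
    agb: pd.DataFrame,
    design: FieldDesign,
) -> pd.DataFrame:
    """Join plot features with AGB and treatment labels into sample rows.

    ``agb`` must carry plot_id, stage and agb_kg_ha; the result has one
    row per (plot, stage) with label columns plus all feature columns.
    """
    labels = design.to_frame()[["plot_id", "n_level", "variety", "replicate"]]
    table = agb.merge(labels, on="plot_id", how="left").merge(
        features, left_on="plot_id", right_index=True, how="left"
    )
    feature_cols = [c for c in features.columns]
    if table[feature_cols].isna().any().any():
        raise ModelingError("missing feature values after join")
    if (table[TARGET_COLUMN] <= 0).any():
        raise ModelingError("AGB values must be positive")
    return table


def feature_columns(table: pd.DataFrame) -> list[str]:
    """All non-label, non-target columns of a feature table."""
    skip = set(LABEL_COLUMNS) | {TARGET_COLUMN}
    return [c for c in table.columns if c not in skip]


# ---------------------------------------------------------------------------
# Train/validation split
# ---------------------------------------------------------------------------

def split_samples(
    table: pd.DataFrame,
    split_fraction: float = 0.7,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified-by-stage random split into calibration and validation.

    The calibration size is round(split_fraction x n) with .5 rounded up
    (toward calibration); strata are the stage labels, allocated by
    largest remainder so stratum proportions track the global fraction.
    Falls back to an unstratified split when any stratum has < 2 samples.
    """
    n = len(table)
    if n < 5:
        raise ModelingError("need at least 5 samples to split")
    if not 0.0 < split_fraction < 1.0:
        raise ModelingError("split_fraction must be in (0, 1)")
    n_cal = int(math.floor(split_fraction * n + 0.5))
    rng = np.random.default_rng(seed)

    if "stage" in table.columns:
        strata = [idx for _, idx in table.groupby("stage", sort=True).groups.items()]
    else:
        strata = [table.index]
    if any(len(s) < 2 for s in strata) and len(strata) > 1:
        warnings.warn(
            "a stratum has fewer than 2 samples; falling back to an "
            "unstratified split",
            stacklevel=2,
        )
        strata = [table.index]

    # Largest-remainder allocation of n_cal across strata.
    quotas = [split_fraction * len(s) for s in strata]
    counts = [int(math.floor(q)) for q in quotas]
    remainder = n_cal - sum(counts)
    order = np.argsort([-(q - math.floor(q)) for q in quotas])
    for k in range(abs(remainder)):
        counts[order[k % len(strata)]] += 1 if remainder > 0 else -1

    cal_idx: list = []
    val_idx: list = []
    for s, c in zip(strata, counts):
        perm = rng.permutation(len(s))
        idx = np.asarray(s)[perm]
        cal_idx.extend(idx[:c])
        val_idx.extend(idx[c:])
    return table.loc[cal_idx], table.loc[val_idx]


# ---------------------------------------------------------------------------
# Random-forest configuration and fitting
# ---------------------------------------------------------------------------

def default_mtry_grid(n_features: int, max_candidates: int = 15) -> tuple[int, ...]:
    """Integers 1..min(n_features, 30), thinned to <= max_candidates."""
    hi = min(n_features, 30)
    values = np.unique(np.round(np.linspace(1, hi, min(hi, max_candidates))))
    return tuple(int(v) for v in values)


@dataclass(frozen=True)
class RFConfig:
    """Random-forest protocol settings."""

    ntree: int = 1000
    mtry_grid: tuple[int, ...] | None = None  # None -> default grid
    split_fraction: float = 0.7
    cv_folds: int = 5
    seed: int = 0
    importance_repeats: int = 5

    def grid_for(self, n_features: int) -> tuple[int, ...]:
        if self.mtry_grid is None:
            return default_mtry_grid(n_features)
        bad = [m for m in self.mtry_grid if not 1 <= m <= n_features]
        if bad:
            raise ModelingError(f"mtry values {bad} outside [1, {n_features}]")
        return tuple(self.mtry_grid)


@dataclass
class ModelResult:
    """Fitted-model evaluation plus per-feature importance."""

    calibration: dict[str, float]
    validation: dict[str, float]
    mtry: int
    importance: dict[str, float]
    feature_names: list[str]
    model: RandomForestRegressor = field(repr=False, default=None)

    def to_dict(self) -> dict:
        return {
            "calibration": self.calibration,
            "validation": self.validation,
            "mtry": self.mtry,
            "importance": self.importance,
        }


def _fit_rf(
    X: np.ndarray, y: np.ndarray, ntree: int, mtry: int, seed: int
) -> RandomForestRegressor:
    model = RandomForestRegressor(
        n_estimators=ntree,
        max_features=mtry,
        random_state=seed,
        bootstrap=True,
        n_jobs=1,
    )
    model.fit(X, y)
    return model


def tune_mtry(
    calibration: pd.DataFrame,
    rf_config: RFConfig,
    feature_cols: list[str] | None = None,
) -> int:
    """Grid-search mtry by k-fold CV on the calibration set.

    Selects the highest mean CV R^2; ties break toward the lowest mean CV
    RMSE, then the smallest mtry.
    """
    cols = feature_cols or feature_columns(calibration)
    grid = rf_config.grid_for(len(cols))
    if not grid:
        raise ModelingError("empty mtry grid")
    if len(grid) == 1:
        return grid[0]
    X = calibration[cols].to_numpy(dtype=float)
    y = calibration[TARGET_COLUMN].to_numpy(dtype=float)
    folds = min(rf_config.cv_folds, len(y))
    kf = KFold(n_splits=folds, shuffle=True, random_state=rf_config.seed)
    splits = list(kf.split(X))

    results = []
    for mtry in grid:
        obs_all, est_all = [], []
        for k, (tr, te) in enumerate(splits):
            model = _fit_rf(
                X[tr], y[tr], rf_config.ntree, mtry, derive_seed(rf_config.seed, "cv", mtry, k)
            )
            obs_all.append(y[te])
            est_all.append(model.predict(X[te]))
        obs = np.concatenate(obs_all)
        est = np.concatenate(est_all)
        results.append((r2_score_pearson(obs, est), -rmse(obs, est), -mtry))
    best = max(range(len(grid)), key=lambda k: results[k])
    return grid[best]


def permutation_importance(
    model: RandomForestRegressor,
    X: np.ndarray,
    y: np.ndarray,
    feature_names: list[str],
    seed: int = 0,
    n_repeats: int = 5,
) -> dict[str, float]:
    """Permutation %IncMSE on a held-out evaluation set.

    For each feature the column is permuted ``n_repeats`` times and the
    mean increase in MSE is expressed as a percentage of the unpermuted
    model MSE; larger values mean more important predictors.
    """
    rng = np.random.default_rng(seed)
    base_mse = float(np.mean((model.predict(X) - y) ** 2))
    if base_mse == 0:
        base_mse = 1e-12
    scores = {}
    for k, name in enumerate(feature_names):
        deltas = []
        for _ in range(n_repeats):
            Xp = X.copy()
            Xp[:, k] = rng.permutation(Xp[:, k])
            mse = float(np.mean((model.predict(Xp) - y) ** 2))
            deltas.append(mse - base_mse)
        scores[name] = 100.0 * float(np.mean(deltas)) / base_mse
    return scores


def fit_and_evaluate(
    calibration: pd.DataFrame,
    validation: pd.DataFrame,
    rf_config: RFConfig,
    feature_cols: list[str] | None = None,
    mtry: int | None = None,
) -> ModelResult:
    """Tune (unless given), fit and evaluate the RF on both sample sets."""
    cols = feature_cols or feature_columns(calibration)
    missing = [c for c in cols if c not in validation.columns]
    if missing:
        raise ModelingError(f"validation set missing feature(s): {missing[:5]}")
    if mtry is None:
        mtry = tune_mtry(calibration, rf_config, cols)

    X_cal = calibration[cols].to_numpy(dtype=float)
    y_cal = calibration[TARGET_COLUMN].to_numpy(dtype=float)
    X_val = validation[cols].to_numpy(dtype=float)
    y_val = validation[TARGET_COLUMN].to_numpy(dtype=float)

    model = _fit_rf(X_cal, y_cal, rf_config.ntree, mtry, derive_seed(rf_config.seed, "fit"))
    importance = permutation_importance(
        model,
        X_val,
        y_val,
        cols,
        seed=derive_seed(rf_config.seed, "perm"),
        n_repeats=rf_config.importance_repeats,
    )
    return ModelResult(
        calibration=evaluation_metrics(y_cal, model.predict(X_cal)),
        validation=evaluation_metrics(y_val, model.predict(X_val)),
        mtry=int(mtry),
        importance=importance,
        feature_names=list(cols),
        model=model,
    )


def run_protocol(
    table: pd.DataFrame,
    rf_config: RFConfig,
    feature_cols: list[str] | None = None,
) -> ModelResult:
    """Split, tune, fit and evaluate in one call."""
    cal, val = split_samples(table, rf_config.split_fraction, rf_config.seed)
    return fit_and_evaluate(cal, val, rf_config, feature_cols)
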