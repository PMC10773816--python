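"""PCA band compression and the sliding-window GLCM texture engine.

The texture pipeline mirrors standard crop-canopy texture practice:

1. the standardized band stack is compressed by PCA and the leading
   components (cumulative explained variance strictly exceeding a
   threshold, default 90%) are retained as grey-scale "component images";
2. each component image is linearly quantized to ``Ng`` grey levels;
3. for every pixel, the grey-level co-occurrence matrix (GLCM) of its
   centred window is accumulated at a fixed displacement and direction,
   and eight Haralick statistics are evaluated on it:
   Mean, Var, Hom, Con, Dis, Ent, SM and Cor;
4. the four directional rasters (0, 45, 90, 135 degrees) are averaged
   pixel-wise into a non-directional (ND) raster.

A full sweep over 2 components x 8 features x 3 windows x 5 directions
yields 240 texture rasters per scene.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from sklearn.decomposition import PCA

from . import _fast
from .scene import MultispectralScene

#: Feature names in engine output order.
FEATURES: tuple[str, ...] = _fast.FEATURE_ORDER

#: Pixel offsets (drow, dcol) per direction label, for displacement 1.
#: 0 deg runs along the image row axis (parallel to planting rows);
#: angles grow counter-clockwise in image coordinates.
DIRECTION_OFFSETS: dict[str, tuple[int, int]] = {
    "D1": (0, 1),    # 0 deg
    "D2": (-1, 1),   # 45 deg
    "D3": (-1, 0),   # 90 deg
    "D4": (-1, -1),  # 135 deg
}

DIRECTIONS: tuple[str, ...] = ("D1", "D2", "D3", "D4")

#: Window-size labels: small / medium / large.
WINDOW_LABELS: dict[int, str] = {3: "S", 7: "M", 13: "L"}


def window_label(window_px: int) -> str:
    """Label for a window size: S/M/L for 3/7/13, else ``W{n}``."""
    return WINDOW_LABELS.get(window_px, f"W{window_px}")


class TextureError(ValueError):
    """Invalid input to the texture engine."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GLCMConfig:
    """Parameters of one GLCM texture computation cell."""

    window_px: int = 3
    direction: str = "D1"
    displacement_px: int = 1
    levels: int = 32
    symmetric: bool = True

    def __post_init__(self) -> None:
        if self.window_px < 3 or self.window_px % 2 == 0:
            raise TextureError("window_px must be an odd integer >= 3")
        if self.direction not in DIRECTIONS and self.direction != "ND":
            raise TextureError(f"unknown direction {self.direction!r}")
        if not 1 <= self.displacement_px < self.window_px:
            raise TextureError("displacement_px must be in [1, window_px)")
        if self.levels < 2:
            raise TextureError("levels must be >= 2")

    @property
    def offset(self) -> tuple[int, int]:
        """(drow, dcol) pixel offset of the co-occurring pair."""
        if self.direction == "ND":
            raise TextureError("ND has no single pixel offset")
        dr, dc = DIRECTION_OFFSETS[self.direction]
        return dr * self.displacement_px, dc * self.displacement_px


@dataclass(frozen=True)
class GLCMGrid:
    """The full window-size x direction sweep grid."""

    windows: tuple[int, ...] = (3, 7, 13)
    directions: tuple[str, ...] = DIRECTIONS
    include_nd: bool = True
    displacement_px: int = 1
    levels: int = 32
    symmetric: bool = True

    def cell(self, window_px: int, direction: str) -> GLCMConfig:
        return GLCMConfig(
            window_px=window_px,
            direction=direction,
            displacement_px=self.displacement_px,
            levels=self.levels,
            symmetric=self.symmetric,
        )

    @property
    def direction_labels(self) -> tuple[str, ...]:
        """Directions reported in sweeps, ND last when enabled."""
        labels = tuple(self.directions)
        if self.include_nd:
            labels = labels + ("ND",)
        return labels


# ---------------------------------------------------------------------------
# PCA band compression
# ---------------------------------------------------------------------------

@dataclass
class PcaResult:
    """PCA of the standardized band stack of one scene.

    ``component_images`` holds score images for *all* components on the
    full scene grid; ``n_selected`` is the number of leading components
    whose cumulative explained-variance ratio strictly exceeds
    ``cumulative_threshold``.
    """

    component_images: list[np.ndarray]
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    cumulative_threshold: float
    n_selected: int
    band_means: np.ndarray = field(default=None, repr=False)
    band_stds: np.ndarray = field(default=None, repr=False)

    def selected_images(self) -> list[np.ndarray]:
        return self.component_images[: self.n_selected]


def pca_compress(
    scene: MultispectralScene,
    mask: np.ndarray | None = None,
    threshold: float = 0.90,
) -> PcaResult:
    """Fit PCA on standardized in-mask band vectors; score the whole scene.

    Bands are z-scored with the mask-pixel mean and standard deviation, so
    the PCA operates on the band correlation structure rather than raw
    dynamic ranges.  Component selection keeps the smallest ``k`` whose
    cumulative explained-variance ratio strictly exceeds ``threshold``.
    """
    if scene.n_bands < 2:
        raise TextureError("PCA needs a scene with at least 2 bands")
    pixels = scene.bands.reshape(scene.n_bands, -1).T  # (npix, nbands)
    if mask is None:
        sel = pixels
    else:
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != scene.shape:
            raise TextureError("mask shape does not match scene grid")
        sel = pixels[mask.ravel()]
    if sel.shape[0] < 5:
        raise TextureError("mask selects fewer than 5 pixels")

    means = sel.mean(axis=0)
    stds = sel.std(axis=0)
    zero_var = np.flatnonzero(stds == 0)
    if zero_var.size:
        names = [scene.band_names[i] for i in zero_var]
        raise TextureError(f"zero-variance band(s) under mask: {names}")

    pca = PCA(n_components=scene.n_bands, svd_solver="full")
    pca.fit((sel - means) / stds)
    scores = pca.transform((pixels - means) / stds)

    evr = pca.explained_variance_ratio_
    cumulative = np.cumsum(evr)
    exceeds = cumulative > threshold
    n_selected = int(np.argmax(exceeds)) + 1 if exceeds.any() else scene.n_bands

    images = [
        scores[:, k].reshape(scene.shape) for k in range(scene.n_bands)
    ]
    return PcaResult(
        component_images=images,
        loadings=pca.components_.T,  # (n_bands, k)
        explained_variance_ratio=evr,
        cumulative_threshold=threshold,
        n_selected=n_selected,
        band_means=means,
        band_stds=stds,
    )


# ---------------------------------------------------------------------------
# Quantization
# ---------------------------------------------------------------------------

def quantize(
    image: np.ndarray,
    levels: int = 32,
    value_range: tuple[float, float] | None = None,
) -> np.ndarray:
    """Linearly bin an image into ``levels`` integer grey levels.

    The global ``[min, max]`` of the image (or an explicit ``value_range``)
    is split into equal-width bins mapped to ``0 .. levels-1``.  A constant
    image maps entirely to level 0.
    """
    if levels < 2:
        raise TextureError("levels must be >= 2")
    image = np.asarray(image, dtype=np.float64)
    if not np.all(np.isfinite(image)):
        raise TextureError("image contains non-finite values")
    if value_range is None:
        lo, hi = float(image.min()), float(image.max())
    else:
        lo, hi = map(float, value_range)
    if hi <= lo:
        return np.zeros(image.shape, dtype=np.int32)
    q = np.floor((image - lo) / (hi - lo) * levels).astype(np.int32)
    return np.clip(q, 0, levels - 1)


# ---------------------------------------------------------------------------
# Single-window GLCM and Haralick statistics
# ---------------------------------------------------------------------------

@dataclass
class GLCMatrix:
    """A normalized grey-level co-occurrence matrix with provenance."""

    matrix: np.ndarray
    direction: str
    displacement: int
    symmetric: bool


def glcm_window(
    level_window: np.ndarray,
    direction: str,
    displacement: int = 1,
    symmetric: bool = True,
    levels: int | None = None,
) -> GLCMatrix:
    """Co-occurrence matrix of a single quantized window.

    Counts pairs of grey levels at the pixel offset implied by
    ``(direction, displacement)``; in symmetric mode each pair is also
    counted in reverse order.  The matrix is normalized to sum to 1.
    """
    w = np.asarray(level_window)
    if w.ndim != 2 or not np.issubdtype(w.dtype, np.integer):
        raise TextureError("level_window must be a 2-D integer array")
    if levels is None:
        levels = int(w.max()) + 1
    if w.min() < 0 or w.max() >= levels:
        raise TextureError("window levels out of range [0, levels)")

    dr, dc = DIRECTION_OFFSETS[direction]
    dr *= displacement
    dc *= displacement
    rows, cols = w.shape
    r_lo, r_hi = max(0, -dr), rows - max(0, dr)
    c_lo, c_hi = max(0, -dc), cols - max(0, dc)
    if r_hi <= r_lo or c_hi <= c_lo:
        raise TextureError(
            "no valid pixel pairs: window too small for displacement "
            f"{displacement} in direction {direction}"
        )
    a = w[r_lo:r_hi, c_lo:c_hi].ravel()
    b = w[r_lo + dr : r_hi + dr, c_lo + dc : c_hi + dc].ravel()

    mat = np.zeros((levels, levels), dtype=np.float64)
    np.add.at(mat, (a, b), 1.0)
    if symmetric:
        np.add.at(mat, (b, a), 1.0)
    mat /= mat.sum()
    return GLCMatrix(
        matrix=mat,
        direction=direction,
        displacement=displacement,
        symmetric=symmetric,
    )


def haralick_features(glcm: GLCMatrix | np.ndarray) -> dict[str, float]:
    """The eight Haralick statistics of a normalized GLCM.

    With P(i, j) the pair probabilities and marginal moments
    mu_i = sum i P(i,j), sigma_i^2 = sum (i - mu_i)^2 P(i,j):

    - Mean = mu_i
    - Var  = sigma_i^2
    - Hom  = sum P(i,j) / (1 + (i-j)^2)
    - Con  = sum (i-j)^2 P(i,j)
    - Dis  = sum |i-j| P(i,j)
    - Ent  = -sum P(i,j) ln P(i,j)   (0 ln 0 == 0)
    - SM   = sum P(i,j)^2
    - Cor  = (sum i j P(i,j) - mu_i mu_j) / (sigma_i sigma_j),
      defined as 0 when either sigma vanishes (constant window).
    """
    p = glcm.matrix if isinstance(glcm, GLCMatrix) else np.asarray(glcm)
    total = p.sum()
    if abs(total - 1.0) > 1e-6:
        raise TextureError(f"GLCM not normalized (sum = {total})")

    n = p.shape[0]
    i = np.arange(n)[:, None]
    j = np.arange(n)[None, :]
    diff = i - j

    mu_i = float((i * p).sum())
    mu_j = float((j * p).sum())
    var_i = float(((i - mu_i) ** 2 * p).sum())
    var_j = float(((j - mu_j) ** 2 * p).sum())

    nz = p > 0
    ent = float(-(p[nz] * np.log(p[nz])).sum())

    denom = np.sqrt(var_i) * np.sqrt(var_j)
    if denom > 1e-12:
        cor = float(((i * j * p).sum() - mu_i * mu_j) / denom)
    else:
        cor = 0.0

    return {
        "Mean": mu_i,
        "Var": var_i,
        "Hom": float((p / (1.0 + diff**2)).sum()),
        "Con": float((diff**2 * p).sum()),
        "Dis": float((np.abs(diff) * p).sum()),
        "Ent": ent,
        "SM": float((p**2).sum()),
        "Cor": cor,
    }


# ---------------------------------------------------------------------------
# Sliding-window texture images
# ---------------------------------------------------------------------------

def texture_image(
    component_image: np.ndarray,
    config: GLCMConfig,
    prequantized: bool = False,
) -> dict[str, np.ndarray]:
    """Per-pixel Haralick feature rasters for one (window, direction) cell.

    The component image is quantized with a single global range (unless
    ``prequantized``), reflect-padded by half the window, and the GLCM of
    every centred window is evaluated, so every output raster is aligned
    with the input grid.
    """
    if config.direction == "ND":
        raise TextureError("use nd_average to build the ND rasters")
    img = np.asarray(component_image)
    if img.ndim != 2:
        raise TextureError("component_image must be 2-D")
    if config.window_px > min(img.shape):
        raise TextureError(
            f"window {config.window_px} exceeds image shape {img.shape}"
        )
    if prequantized:
        q = np.ascontiguousarray(img, dtype=np.int32)
        if q.min() < 0 or q.max() >= config.levels:
            raise TextureError("prequantized levels out of range")
    else:
        q = quantize(img, config.levels)

    half = config.window_px // 2
    padded = np.pad(q, half, mode="reflect")
    dr, dc = config.offset
    maps = _fast.glcm_feature_maps(
        padded, dr, dc, config.window_px, config.levels, config.symmetric
    )
    return {name: maps[k] for k, name in enumerate(FEATURES)}


def nd_average(
    directional: dict[str, dict[str, np.ndarray]],
) -> dict[str, np.ndarray]:
    """Pixel-wise mean of the four directional feature rasters.

    ``directional`` maps direction label -> {feature -> raster}; all four
    directions must be present with identical feature keys and shapes.
    """
    missing = [d for d in DIRECTIONS if d not in directional]
    if missing:
        raise TextureError(f"missing direction(s) for ND average: {missing}")
    out: dict[str, np.ndarray] = {}
    for feat in FEATURES:
        stack = [directional[d][feat] for d in DIRECTIONS]
        shapes = {s.shape for s in stack}
        if len(shapes) != 1:
            raise TextureError(f"misaligned rasters for feature {feat}")
        out[feat] = np.mean(stack, axis=0)
    return out


# ---------------------------------------------------------------------------
# Full texture stack
# ---------------------------------------------------------------------------

def stack_key(component: int, feature: str, window_px: int, direction: str) -> str:
    """Canonical raster key, e.g. ``PC1_Con_S_D2``."""
    return f"PC{component}_{feature}_{window_label(window_px)}_{direction}"


class TextureStack(dict):
    """Mapping of ``PC{c}_{feature}_{S|M|L}_{D1..D4|ND}`` -> 2-D raster."""

    def select(
        self,
        component: int | None = None,
        feature: str | None = None,
        window: str | None = None,
        direction: str | None = None,
    ) -> "TextureStack":
        """Sub-stack matching the given key fields (None = any)."""
        out = TextureStack()
        for key, raster in self.items():
            pc, feat, win, direc = key.split("_")
            if component is not None and pc != f"PC{component}":
                continue
            if feature is not None and feat != feature:
                continue
            if window is not None and win != window:
                continue
            if direction is not None and direc != direction:
                continue
            out[key] = raster
        return out


def build_full_stack(
    pca_result: PcaResult,
    grid: GLCMGrid = GLCMGrid(),
) -> TextureStack:
    """Texture rasters for every (component, feature, window, direction).

    Each selected PCA component image is quantized once (global range),
    then swept over all windows and directions; ND rasters are appended as
    the per-pixel mean of the four directional ones.  The key count is
    ``n_selected x 8 x |windows| x (|directions| + 1)``.
    """
    if pca_result.n_selected < 1:
        raise TextureError("PCA selected no components")
    stack = TextureStack()
    for c, image in enumerate(pca_result.selected_images(), start=1):
        q = quantize(image, grid.levels)
        for window_px in grid.windows:
            directional: dict[str, dict[str, np.ndarray]] = {}
            for direction in grid.directions:
                cfg = grid.cell(window_px, direction)
                directional[direction] = texture_image(
                    q, cfg, prequantized=True
                )
                for feat, raster in directional[direction].items():
                    stack[stack_key(c, feat, window_px, direction)] = raster
            if grid.include_nd:
                for feat, raster in nd_average(directional).items():
                    stack[stack_key(c, feat, window_px, "ND")] = raster
    return stack
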