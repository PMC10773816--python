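"""Synthetic row-crop multispectral scenes, field design and biomass.

Emulates the data a UAV multispectral campaign over a small-plot rice
nitrogen trial produces, at desk scale:

* a randomized split-plot field layout (4 N levels x 3 varieties x 3
  replicates = 36 plots) rendered on a pixel grid;
* per-stage five-band reflectance scenes in which plants sit on the
  row/plant lattice (30 cm row, 15 cm plant spacing at ~1.7 cm GSD) as
  soft-edged discs over a two-phase soil/water background, with sensor
  noise;
* plot-level aboveground biomass (AGB, kg/ha) increasing with stage and
  nitrogen level, coupled to canopy cover so texture carries signal;
* calibration-panel observations with known per-band gain/offset.

Canopy cover, plant size, band reflectances and AGB magnitudes are
configured per growth stage (late tillering LT, booting B, heading to
flowering HtF, early filling EF).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import ndimage

from .scene import DEFAULT_BANDS, MultispectralScene

STAGES: tuple[str, ...] = ("LT", "B", "HtF", "EF")


class LayoutError(ValueError):
    """Field layout does not fit or is inconsistent."""


class ParameterError(ValueError):
    """Invalid generator parameter."""


# ---------------------------------------------------------------------------
# Field design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlotSpec:
    """One experimental plot: treatment labels plus its raster footprint."""

    plot_id: str
    n_level: str
    variety: str
    replicate: int
    pixel_region: tuple[int, int, int, int]  # row0, row1, col0, col1 (half-open)


@dataclass
class FieldDesign:
    """The full plot grid of one field trial."""

    plots: list[PlotSpec]
    n_levels: tuple[str, ...]
    varieties: tuple[str, ...]
    replicates: int
    plot_shape_px: tuple[int, int]
    buffer_px: int
    scene_shape_px: tuple[int, int]

    def __post_init__(self) -> None:
        expected = len(self.n_levels) * len(self.varieties) * self.replicates
        if len(self.plots) != expected:
            raise LayoutError(
                f"{len(self.plots)} plots for a "
                f"{len(self.n_levels)}x{len(self.varieties)}x{self.replicates} design"
            )
        if self.buffer_px < 0 or any(
            2 * self.buffer_px >= s for s in self.plot_shape_px
        ):
            raise LayoutError("buffer_px must be >= 0 and < half the plot footprint")
        rows, cols = self.scene_shape_px
        boxes = []
        for p in self.plots:
            r0, r1, c0, c1 = p.pixel_region
            if not (0 <= r0 < r1 <= rows and 0 <= c0 < c1 <= cols):
                raise LayoutError(f"plot {p.plot_id} outside scene bounds")
            boxes.append(p.pixel_region)
        for (a, b) in itertools.combinations(boxes, 2):
            if a[0] < b[1] and b[0] < a[1] and a[2] < b[3] and b[2] < a[3]:
                raise LayoutError("plot footprints overlap")

    def plot_mask(self) -> np.ndarray:
        """Boolean raster that is True inside any (unbuffered) plot."""
        mask = np.zeros(self.scene_shape_px, dtype=bool)
        for p in self.plots:
            r0, r1, c0, c1 = p.pixel_region
            mask[r0:r1, c0:c1] = True
        return mask

    def buffered_region(self, plot: PlotSpec) -> tuple[int, int, int, int]:
        """Plot footprint shrunk inward by ``buffer_px`` on every edge."""
        r0, r1, c0, c1 = plot.pixel_region
        b = self.buffer_px
        return r0 + b, r1 - b, c0 + b, c1 - b

    def to_frame(self) -> pd.DataFrame:
        rows = [
            {
                "plot_id": p.plot_id,
                "n_level": p.n_level,
                "variety": p.variety,
                "replicate": p.replicate,
                "row0": p.pixel_region[0],
                "row1": p.pixel_region[1],
                "col0": p.pixel_region[2],
                "col1": p.pixel_region[3],
            }
            for p in self.plots
        ]
        return pd.DataFrame(rows)


def generate_field_layout(
    n_levels: tuple[str, ...] = ("N0", "N1", "N2", "N3"),
    varieties: tuple[str, ...] = ("V1", "V2", "V3"),
    replicates: int = 3,
    plot_shape_px: tuple[int, int] = (64, 256),
    buffer_px: int = 6,
    scene_margin_px: int = 8,
    seed: int = 0,
    gap_px: int = 4,
    scene_shape_px: tuple[int, int] | None = None,
) -> FieldDesign:
    """Lay the split-plot design out on a non-overlapping pixel grid.

    Replicate blocks are stacked vertically; inside a block the nitrogen
    main plots run left to right in seed-randomized order and the variety
    subplots are stacked within each main plot, again seed-randomized.
    If ``scene_shape_px`` is given the grid must fit inside it, otherwise
    the scene is sized to the grid plus margins.
    """
    if replicates < 1 or not n_levels or not varieties:
        raise ParameterError("all design counts must be >= 1")
    rng = np.random.default_rng(seed)
    ph, pw = plot_shape_px

    n_block_rows = replicates
    n_sub_rows = len(varieties)
    n_cols = len(n_levels)
    total_rows = scene_margin_px * 2 + n_block_rows * n_sub_rows * ph + (
        n_block_rows * n_sub_rows - 1
    ) * gap_px
    total_cols = scene_margin_px * 2 + n_cols * pw + (n_cols - 1) * gap_px
    if scene_shape_px is None:
        scene_shape_px = (total_rows, total_cols)
    elif total_rows > scene_shape_px[0] or total_cols > scene_shape_px[1]:
        raise LayoutError(
            f"plot grid {total_rows}x{total_cols} exceeds scene "
            f"bounds {scene_shape_px[0]}x{scene_shape_px[1]}"
        )

    plots: list[PlotSpec] = []
    for rep in range(1, replicates + 1):
        n_order = list(rng.permutation(np.asarray(n_levels)))
        for col_idx, n_level in enumerate(n_order):
            v_order = list(rng.permutation(np.asarray(varieties)))
            for sub_idx, variety in enumerate(v_order):
                grid_row = (rep - 1) * n_sub_rows + sub_idx
                r0 = scene_margin_px + grid_row * (ph + gap_px)
                c0 = scene_margin_px + col_idx * (pw + gap_px)
                plots.append(
                    PlotSpec(
                        plot_id=f"{n_level}_{variety}_R{rep}",
                        n_level=str(n_level),
                        variety=str(variety),
                        replicate=rep,
                        pixel_region=(r0, r0 + ph, c0, c0 + pw),
                    )
                )
    return FieldDesign(
        plots=plots,
        n_levels=tuple(n_levels),
        varieties=tuple(varieties),
        replicates=replicates,
        plot_shape_px=plot_shape_px,
        buffer_px=buffer_px,
        scene_shape_px=scene_shape_px,
    )


# ---------------------------------------------------------------------------
# Stage parameters
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class StageParams:
    """Per-growth-stage generator settings.

    ``band_reflectance_background`` is the soil end-member; the background
    is a two-phase soil/water mixture with ``water_fraction`` of the
    background area drawn as water blobs.  ``cover_multiplier_by_n``
    modulates canopy cover with nitrogen level so that within-stage cover
    (and hence texture) varies across plots in step with AGB.
    """

    stage: str
    canopy_cover_fraction: float
    plant_radius_px: float
    band_reflectance_canopy: tuple[float, ...]
    band_reflectance_background: tuple[float, ...]
    band_reflectance_water: tuple[float, ...]
    water_fraction: float
    noise_sd: float
    agb_mean_by_n: dict
    agb_cv: float
    cover_multiplier_by_n: dict = field(
        default_factory=lambda: {"N0": 0.75, "N1": 0.92, "N2": 1.05, "N3": 1.15}
    )
    cover_jitter: float = 0.04
    max_cover: float = 0.97
    #: Multiplicative leaf-scale texture amplitude on canopy pixels.
    #: The realized per-plot amplitude grows with canopy density (leaf
    #: layering and internal shadowing) until the canopy closes.
    canopy_texture_sd: float = 0.12
    #: Cover fraction at which leaf-layering contrast saturates.
    canopy_texture_saturation: float = 0.65
    #: Lognormal sigma of the per-plot canopy texture amplitude.  Young
    #: leaf canopies are uniform (0 early); after heading the panicle
    #: mottling state varies strongly from plot to plot.
    canopy_texture_jitter: float = 0.0
    #: Multiplicative fine-scale speckle amplitude on background pixels
    #: (water glint / wet-soil clods; strongest on the flooded early field).
    background_texture_sd: float = 0.10
    #: Between-plot sd of the water fraction: paddy water depth is uneven,
    #: so the visible soil/water balance varies from plot to plot
    #: independently of treatment.
    water_fraction_jitter: float = 0.15
    #: Lognormal sigma of the per-plot background speckle amplitude:
    #: glint and surface-drying state differ between plots independently
    #: of treatment.
    background_texture_jitter: float = 0.5

    def __post_init__(self) -> None:
        if not 0.0 <= self.canopy_cover_fraction <= 1.0:
            raise ParameterError("canopy_cover_fraction must be in [0, 1]")
        for name in (
            "band_reflectance_canopy",
            "band_reflectance_background",
            "band_reflectance_water",
        ):
            vals = getattr(self, name)
            if any(not 0.0 <= v <= 1.0 for v in vals):
                raise ParameterError(f"{name} values must be in [0, 1]")
        if self.noise_sd < 0:
            raise ParameterError("noise_sd must be >= 0")
        if self.agb_cv < 0:
            raise ParameterError("agb_cv must be >= 0")
        if any(m < 0 for m in self.agb_mean_by_n.values()):
            raise ParameterError("agb means must be >= 0")


def default_stage_params() -> dict[str, StageParams]:
    """The default four-stage season.

    Canopy cover rises from a partly closed early canopy to a nearly
    closed late one; water recedes and soil dries through the season; AGB
    means per nitrogen level rise from a ~1900 kg/ha stage mean at late
    tillering to ~11200 kg/ha at early filling with a between-N-level
    coefficient of variation around 0.5.
    """
    soil = {
        "LT": (0.06, 0.09, 0.11, 0.15, 0.18),
        "B": (0.07, 0.10, 0.13, 0.17, 0.21),
        "HtF": (0.08, 0.11, 0.14, 0.19, 0.23),
        "EF": (0.09, 0.13, 0.16, 0.21, 0.25),
    }
    # Water is rendered as a darker version of the local soil spectrum: the
    # two background phases differ in brightness, not spectral shape, which
    # keeps the band manifold two-dimensional (canopy contrast + background
    # brightness) the way a canopy/soil/water paddy scene compresses into
    # two leading principal components.
    water = {k: tuple(0.45 * v for v in soil[k]) for k in soil}
    canopy = {
        "LT": (0.03, 0.08, 0.05, 0.28, 0.42),
        "B": (0.03, 0.09, 0.05, 0.33, 0.48),
        "HtF": (0.04, 0.09, 0.06, 0.34, 0.50),
        "EF": (0.05, 0.10, 0.08, 0.33, 0.47),
    }
    cover = {"LT": 0.35, "B": 0.65, "HtF": 0.80, "EF": 0.90}
    radius = {"LT": 7.0, "B": 11.0, "HtF": 13.0, "EF": 15.0}
    water_frac = {"LT": 0.50, "B": 0.40, "HtF": 0.30, "EF": 0.20}
    agb = {
        "LT": {"N0": 700.0, "N1": 1400.0, "N2": 2300.0, "N3": 3300.0},
        "B": {"N0": 2800.0, "N1": 5700.0, "N2": 9300.0, "N3": 13400.0},
        "HtF": {"N0": 3400.0, "N1": 6800.0, "N2": 11100.0, "N3": 16000.0},
        "EF": {"N0": 4500.0, "N1": 8500.0, "N2": 13400.0, "N3": 18400.0},
    }
    agb_cv = {"LT": 0.18, "B": 0.15, "HtF": 0.14, "EF": 0.12}
    # Fine-scale structure: the flooded early field glints and shows wet
    # soil clods (strong background speckle); as the field dries the
    # background smooths out while the canopy keeps its leaf mosaic.
    bg_texture = {"LT": 0.35, "B": 0.18, "HtF": 0.10, "EF": 0.06}
    # Young leaf canopies are uniform; panicle emergence makes the late
    # canopy surface state vary between plots.
    canopy_jitter = {"LT": 0.0, "B": 0.2, "HtF": 0.35, "EF": 0.6}
    return {
        stage: StageParams(
            stage=stage,
            canopy_cover_fraction=cover[stage],
            plant_radius_px=radius[stage],
            band_reflectance_canopy=canopy[stage],
            band_reflectance_background=soil[stage],
            band_reflectance_water=water[stage],
            water_fraction=water_frac[stage],
            noise_sd=0.005,
            agb_mean_by_n=agb[stage],
            agb_cv=agb_cv[stage],
            background_texture_sd=bg_texture[stage],
            canopy_texture_jitter=canopy_jitter[stage],
        )
        for stage in STAGES
    }


# ---------------------------------------------------------------------------
# Cover fractions shared by scene rendering and AGB simulation
# ---------------------------------------------------------------------------

def _plot_noise_draws(
    design: FieldDesign, seed: int
) -> dict[str, float]:
    """One standard-normal draw per plot (subseed 0 of ``seed``).

    The same draw perturbs a plot's canopy cover and its AGB, which is
    what couples texture to biomass at the replicate level.
    """
    rng = np.random.default_rng(np.random.SeedSequence([seed, 0]))
    return {p.plot_id: float(z) for p, z in zip(design.plots, rng.standard_normal(len(design.plots)))}


def plot_cover_fractions(
    design: FieldDesign, params: StageParams, seed: int
) -> dict[str, float]:
    """Target within-plot canopy cover per plot for one stage.

    cover = stage cover x N-level multiplier x (1 + jitter), clipped to
    ``[0, max_cover]``; the jitter draw is shared with the AGB simulator.
    """
    z = _plot_noise_draws(design, seed)
    covers = {}
    for p in design.plots:
        mult = params.cover_multiplier_by_n.get(p.n_level, 1.0)
        c = params.canopy_cover_fraction * mult * (1.0 + params.cover_jitter * z[p.plot_id])
        covers[p.plot_id] = float(np.clip(c, 0.0, params.max_cover))
    if params.canopy_cover_fraction == 0.0:
        covers = {k: 0.0 for k in covers}
    return covers


# ---------------------------------------------------------------------------
# Scene rendering
# ---------------------------------------------------------------------------

def _stamp_plants(
    shape: tuple[int, int],
    centers: np.ndarray,
    radii: np.ndarray,
    soft_px: float = 1.0,
) -> np.ndarray:
    """Canopy opacity field (0..1) from soft-edged discs."""
    alpha = np.zeros(shape, dtype=np.float64)
    for (cr, cc), r in zip(centers, radii):
        lo_r = max(0, int(np.floor(cr - r - 2)))
        hi_r = min(shape[0], int(np.ceil(cr + r + 3)))
        lo_c = max(0, int(np.floor(cc - r - 2)))
        hi_c = min(shape[1], int(np.ceil(cc + r + 3)))
        if lo_r >= hi_r or lo_c >= hi_c:
            continue
        yy = np.arange(lo_r, hi_r)[:, None] - cr
        xx = np.arange(lo_c, hi_c)[None, :] - cc
        dist = np.sqrt(yy**2 + xx**2)
        patch = np.clip((r - dist) / soft_px + 0.5, 0.0, 1.0)
        np.maximum(alpha[lo_r:hi_r, lo_c:hi_c], patch, out=alpha[lo_r:hi_r, lo_c:hi_c])
    return alpha


def _plot_lattice(
    region: tuple[int, int, int, int],
    row_pitch: float,
    plant_pitch: float,
    rng: np.random.Generator,
    pos_jitter: float = 0.8,
) -> np.ndarray:
    """Plant centres on the row/plant lattice of one plot footprint."""
    r0, r1, c0, c1 = region
    row_positions = np.arange(r0 + row_pitch / 2.0, r1, row_pitch)
    col_positions = np.arange(c0 + plant_pitch / 2.0, c1, plant_pitch)
    grid = np.array([(r, c) for r in row_positions for c in col_positions])
    if len(grid):
        grid = grid + rng.uniform(-pos_jitter, pos_jitter, size=grid.shape)
    return grid


def _cover_radius(
    region_shape: tuple[int, int],
    centers_local: np.ndarray,
    radius_jitter: np.ndarray,
    target_cover: float,
    r_max: float,
) -> float:
    """Bisect the base disc radius to hit the requested plot cover."""

    def realized(r_base: float) -> float:
        alpha = _stamp_plants(region_shape, centers_local, r_base * radius_jitter)
        return float((alpha >= 0.5).mean())

    if realized(r_max) < target_cover - 0.02:
        raise ParameterError(
            f"canopy cover {target_cover:.2f} unreachable with "
            f"plant_radius_px {r_max:.1f} at this lattice"
        )
    lo, hi = 0.0, r_max
    for _ in range(18):
        mid = 0.5 * (lo + hi)
        if realized(mid) < target_cover:
            lo = mid
        else:
            hi = mid
    return hi


def render_scene(
    design: FieldDesign,
    params: StageParams,
    gsd_cm: float = 1.7,
    row_spacing_cm: float = 30.0,
    plant_spacing_cm: float = 15.0,
    seed: int = 0,
) -> MultispectralScene:
    """Render a five-band reflectance scene for one growth stage.

    Plants are soft-edged discs at the row/plant lattice (planting rows
    parallel to the image row axis); the base disc radius is bisected per
    plot so realized cover matches the plot's target cover.  Background is
    a soil/water blob mixture.  Independent Gaussian noise of sd
    ``noise_sd`` is added per band and the result clipped to [0, 1].
    """
    if gsd_cm <= 0:
        raise ParameterError("gsd_cm must be > 0")
    if row_spacing_cm < gsd_cm or plant_spacing_cm < gsd_cm:
        raise ParameterError("spacings must be >= gsd_cm")

    rng = np.random.default_rng(np.random.SeedSequence([seed, 1]))
    covers = plot_cover_fractions(design, params, seed)
    shape = design.scene_shape_px
    row_pitch = row_spacing_cm / gsd_cm
    plant_pitch = plant_spacing_cm / gsd_cm

    # Two-phase soil/water background with smooth within-phase variation.
    # Water depth is uneven across the field, so each plot's visible water
    # fraction is jittered around the stage value (independently of
    # treatment): within a plot the blob field is thresholded at the
    # plot's own quantile.
    blob = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=8.0)
    blob = (blob - blob.mean()) / (blob.std() + 1e-12)
    water_mask = blob < np.quantile(blob, params.water_fraction)
    if params.water_fraction_jitter > 0 and 0 < params.water_fraction < 1:
        for plot in design.plots:
            r0, r1, c0, c1 = plot.pixel_region
            w_p = float(
                np.clip(
                    params.water_fraction
                    + params.water_fraction_jitter * rng.standard_normal(),
                    0.02,
                    0.95,
                )
            )
            local = blob[r0:r1, c0:c1]
            water_mask[r0:r1, c0:c1] = local < np.quantile(local, w_p)
    brightness = 1.0 + 0.10 * ndimage.gaussian_filter(
        rng.standard_normal(shape), sigma=16.0
    )

    soil = np.asarray(params.band_reflectance_background)
    water = np.asarray(params.band_reflectance_water)
    canopy = np.asarray(params.band_reflectance_canopy)
    n_bands = len(soil)

    bands = np.empty((n_bands,) + shape, dtype=np.float64)
    for b in range(n_bands):
        bands[b] = np.where(water_mask, water[b], soil[b] * brightness)

    alpha = np.zeros(shape, dtype=np.float64)
    plant_gain = np.ones(shape, dtype=np.float64)
    realized_cover: dict[str, float] = {}
    for plot in design.plots:
        target = covers[plot.plot_id]
        if target <= 0.0:
            realized_cover[plot.plot_id] = 0.0
            continue
        region = plot.pixel_region
        r0, r1, c0, c1 = region
        centers = _plot_lattice(region, row_pitch, plant_pitch, rng)
        if len(centers) == 0:
            raise ParameterError(f"plot {plot.plot_id} too small for lattice")
        jitter = rng.uniform(0.85, 1.15, size=len(centers))
        local = centers - np.array([r0, c0])
        r_base = _cover_radius(
            (r1 - r0, c1 - c0), local, jitter, target, params.plant_radius_px
        )
        plot_alpha = _stamp_plants(shape, centers, r_base * jitter)
        # Per-plant canopy brightness variation (leaf colour differences).
        gains = rng.uniform(0.88, 1.12, size=len(centers))
        for (cr, cc), r, g in zip(centers, r_base * jitter, gains):
            lo_r, hi_r = max(0, int(cr - r - 2)), min(shape[0], int(cr + r + 3))
            lo_c, hi_c = max(0, int(cc - r - 2)), min(shape[1], int(cc + r + 3))
            plant_gain[lo_r:hi_r, lo_c:hi_c] = g
        np.maximum(alpha, plot_alpha, out=alpha)
        sub = plot_alpha[r0:r1, c0:c1]
        realized_cover[plot.plot_id] = float((sub >= 0.5).mean())

    # Fine-scale multiplicative texture: leaf mosaic on canopy, speckle
    # (water glint / soil clods) on background.  Both scale all bands
    # equally, so the band manifold stays two-dimensional.
    def fine_noise(sigma: float) -> np.ndarray:
        f = ndimage.gaussian_filter(rng.standard_normal(shape), sigma=sigma)
        return f / (f.std() + 1e-12)

    # Leaf-layering contrast grows with canopy density until the canopy
    # closes, so the per-plot texture amplitude tracks plot cover below
    # the saturation point and is flat above it.
    amp = np.zeros(shape, dtype=np.float64)
    sat = params.canopy_texture_saturation
    for plot in design.plots:
        r0, r1, c0, c1 = plot.pixel_region
        rel = min(covers[plot.plot_id], sat) / sat if sat > 0 else 1.0
        if params.canopy_texture_jitter > 0:
            # Post-heading panicle mottling: surface texture amplitude
            # varies between plots independently of treatment.
            rel *= float(np.exp(params.canopy_texture_jitter * rng.standard_normal()))
        amp[r0:r1, c0:c1] = params.canopy_texture_sd * rel
    leaf_tex = 1.0 + amp * fine_noise(1.0)
    # Background speckle is pixel-rough (water glint, soil clods) and its
    # amplitude varies between plots with the local drying/glinting state.
    bg_amp = np.full(shape, params.background_texture_sd)
    if params.background_texture_jitter > 0:
        for plot in design.plots:
            r0, r1, c0, c1 = plot.pixel_region
            bg_amp[r0:r1, c0:c1] = params.background_texture_sd * float(
                np.exp(params.background_texture_jitter * rng.standard_normal())
            )
    bg_tex = 1.0 + bg_amp * fine_noise(0.4)

    for b in range(n_bands):
        bands[b] = (
            bands[b] * bg_tex * (1.0 - alpha)
            + canopy[b] * plant_gain * leaf_tex * alpha
        )
        if params.noise_sd > 0:
            bands[b] += rng.normal(0.0, params.noise_sd, size=shape)
    np.clip(bands, 0.0, 1.0, out=bands)

    scene = MultispectralScene(
        bands=bands.astype(np.float32),
        band_names=DEFAULT_BANDS[:n_bands],
        gsd_cm=gsd_cm,
        kind="reflectance",
    )
    scene.meta["stage"] = params.stage
    scene.meta["target_cover"] = covers
    scene.meta["realized_cover"] = realized_cover
    return scene


# ---------------------------------------------------------------------------
# AGB simulation
# ---------------------------------------------------------------------------

def simulate_agb(
    design: FieldDesign, params: StageParams, seed: int = 0
) -> pd.DataFrame:
    """Per-plot AGB (kg/ha) for one stage.

    AGB = N-level mean x lognormal noise with coefficient of variation
    ``agb_cv``; the underlying normal draw is the same one that jitters
    the plot's canopy cover, so cover and AGB co-vary at replicate level.
    """
    for n in design.n_levels:
        if n not in params.agb_mean_by_n:
            raise ParameterError(f"agb_mean_by_n missing level {n}")
    z = _plot_noise_draws(design, seed)
    sigma = float(np.sqrt(np.log1p(params.agb_cv**2)))
    rows = []
    for p in design.plots:
        noise = np.exp(sigma * z[p.plot_id] - 0.5 * sigma**2)
        rows.append(
            {
                "plot_id": p.plot_id,
                "stage": params.stage,
                "agb_kg_ha": params.agb_mean_by_n[p.n_level] * noise,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Calibration panels
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PanelObservation:
    """One diffuse calibration panel seen in one band."""

    band: str
    dn: float
    reflectance: float


def generate_panels(
    gains_per_band: dict[str, float],
    offsets_per_band: dict[str, float],
    panel_reflectances: tuple[float, ...],
    noise_sd: float = 0.0,
    seed: int = 0,
) -> list[PanelObservation]:
    """Panel observations inverting reflectance = DN x gain + offset.

    DN = (reflectance - offset) / gain plus Gaussian noise of sd
    ``noise_sd`` (DN units); one observation per (band, panel).
    """
    if len(panel_reflectances) < 2:
        raise ParameterError("need at least 2 panels to fit a line")
    if any(g == 0 for g in gains_per_band.values()):
        raise ParameterError("gains must be nonzero")
    rng = np.random.default_rng(seed)
    obs = []
    for band, gain in gains_per_band.items():
        offset = offsets_per_band[band]
        for refl in panel_reflectances:
            dn = (refl - offset) / gain
            if noise_sd > 0:
                dn += rng.normal(0.0, noise_sd)
            obs.append(PanelObservation(band=band, dn=float(dn), reflectance=float(refl)))
    return obs


def panels_to_frame(observations: list[PanelObservation]) -> pd.DataFrame:
    return pd.DataFrame(
        [{"band": o.band, "dn": o.dn, "reflectance": o.reflectance} for o in observations]
    )


# ---------------------------------------------------------------------------
# Whole-season convenience generator
# ---------------------------------------------------------------------------

@dataclass
class Season:
    """A full synthetic campaign: design, per-stage scenes and AGB."""

    design: FieldDesign
    scenes: dict[str, MultispectralScene]
    agb: pd.DataFrame  # plot_id, stage, agb_kg_ha
    seed: int


def stage_seed(master_seed: int, stage: str) -> int:
    """Deterministic per-stage sub-seed below 2**31."""
    idx = STAGES.index(stage) if stage in STAGES else hash(stage) % 97
    return int(np.random.SeedSequence([master_seed, 1000 + idx]).generate_state(1)[0] % (2**31))


def generate_season(
    seed: int = 0,
    design: FieldDesign | None = None,
    stage_params: dict[str, StageParams] | None = None,
    gsd_cm: float = 1.7,
) -> Season:
    """Generate the default four-stage campaign (scenes + AGB table)."""
    if design is None:
        design = generate_field_layout(seed=seed)
    if stage_params is None:
        stage_params = default_stage_params()
    scenes = {}
    agb_tables = []
    for stage, params in stage_params.items():
        s = stage_seed(seed, stage)
        scenes[stage] = render_scene(design, params, gsd_cm=gsd_cm, seed=s)
        agb_tables.append(simulate_agb(design, params, seed=s))
    return Season(
        design=design,
        scenes=scenes,
        agb=pd.concat(agb_tables, ignore_index=True),
        seed=seed,
    )


def scale_stage_params(
    stage_params: dict[str, StageParams], radius_scale: float
) -> dict[str, StageParams]:
    """Rescale plant radii for smaller/larger pixel grids (desk-scale runs)."""
    return {
        k: replace(v, plant_radius_px=v.plant_radius_px * radius_scale)
        for k, v in stage_params.items()
    }
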