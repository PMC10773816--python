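"""Reading and writing scenes, texture stacks and tables.

Multi-band rasters are stored as plain multi-page TIFF via tifffile with
a JSON payload in the ImageDescription tag carrying band names, pixel
size and value semantics.  Tables travel as CSV through pandas.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile

from .scene import MultispectralScene
from .synthetic import FieldDesign, PanelObservation, PlotSpec
from .texture import TextureStack


def write_scene(path: str | Path, scene: MultispectralScene) -> None:
    """Write a scene as a multi-page TIFF (one page per band)."""
    meta = {
        "band_names": list(scene.band_names),
        "gsd_cm": scene.gsd_cm,
        "kind": scene.kind,
    }
    tifffile.imwrite(
        str(path),
        np.asarray(scene.bands),
        description=json.dumps(meta),
        photometric="minisblack",
    )


def read_scene(path: str | Path) -> MultispectralScene:
    with tifffile.TiffFile(str(path)) as tif:
        bands = tif.asarray()
        desc = tif.pages[0].description or "{}"
    meta = json.loads(desc)
    return MultispectralScene(
        bands=bands,
        band_names=tuple(meta.get("band_names", [f"band{i}" for i in range(len(bands))])),
        gsd_cm=float(meta.get("gsd_cm", 1.7)),
        kind=meta.get("kind", "reflectance"),
    )


def write_stack(path: str | Path, stack: TextureStack) -> None:
    """Write a texture stack as a multi-page TIFF keyed by a manifest."""
    keys = sorted(stack)
    data = np.stack([stack[k] for k in keys]).astype(np.float32)
    tifffile.imwrite(
        str(path),
        data,
        description=json.dumps({"keys": keys}),
        photometric="minisblack",
    )


def read_stack(path: str | Path) -> TextureStack:
    with tifffile.TiffFile(str(path)) as tif:
        data = tif.asarray()
        desc = tif.pages[0].description or "{}"
    keys = json.loads(desc)["keys"]
    return TextureStack({k: data[i] for i, k in enumerate(keys)})


def write_layout(path: str | Path, design: FieldDesign) -> None:
    design.to_frame().to_csv(path, index=False)


def read_layout(
    path: str | Path,
    plot_shape_px: tuple[int, int] | None = None,
    buffer_px: int = 6,
    scene_shape_px: tuple[int, int] | None = None,
) -> FieldDesign:
    """Rebuild a FieldDesign from a layout CSV.

    Plot shape is inferred from the first region and scene bounds from
    the region extremes unless given explicitly.
    """
    frame = pd.read_csv(path)
    plots = [
        PlotSpec(
            plot_id=str(r.plot_id),
            n_level=str(r.n_level),
            variety=str(r.variety),
            replicate=int(r.replicate),
            pixel_region=(int(r.row0), int(r.row1), int(r.col0), int(r.col1)),
        )
        for r in frame.itertuples()
    ]
    if plot_shape_px is None:
        p = plots[0].pixel_region
        plot_shape_px = (p[1] - p[0], p[3] - p[2])
    if scene_shape_px is None:
        scene_shape_px = (
            int(frame.row1.max()) + int(frame.row0.min()),
            int(frame.col1.max()) + int(frame.col0.min()),
        )
    return FieldDesign(
        plots=plots,
        n_levels=tuple(sorted(frame.n_level.unique())),
        varieties=tuple(sorted(frame.variety.unique())),
        replicates=int(frame.replicate.max()),
        plot_shape_px=plot_shape_px,
        buffer_px=buffer_px,
        scene_shape_px=scene_shape_px,
    )


def write_panels(path: str | Path, observations: list[PanelObservation]) -> None:
    pd.DataFrame(
        [{"band": o.band, "dn": o.dn, "reflectance": o.reflectance} for o in observations]
    ).to_csv(path, index=False)


def read_panels(path: str | Path) -> list[PanelObservation]:
    frame = pd.read_csv(path)
    return [
        PanelObservation(band=str(r.band), dn=float(r.dn), reflectance=float(r.reflectance))
        for r in frame.itertuples()
    ]
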