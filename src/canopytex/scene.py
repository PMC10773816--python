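"""Shared raster container for multi-band canopy imagery.

A scene is a stack of co-registered single-band rasters (band, row, col)
holding either raw sensor digital numbers (DN) or surface reflectance in
[0, 1].  Band order follows the five-band multispectral convention
blue / green / red / red-edge / near-infrared.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

#: Canonical five-band order: blue, green, red, red edge, near infrared.
DEFAULT_BANDS: tuple[str, ...] = ("B", "G", "R", "RE", "NIR")


@dataclass
class MultispectralScene:
    """A multi-band raster with band names, pixel size and value semantics.

    Parameters
    ----------
    bands
        Array of shape ``(n_bands, n_rows, n_cols)``.
    band_names
        One name per band, in storage order.
    gsd_cm
        Ground sampling distance (pixel edge length) in centimetres.
    kind
        ``"reflectance"`` (float, nominally in [0, 1]) or ``"dn"``
        (raw digital numbers).
    """

    bands: np.ndarray
    band_names: tuple[str, ...] = DEFAULT_BANDS
    gsd_cm: float = 1.7
    kind: str = "reflectance"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.bands = np.asarray(self.bands)
        if self.bands.ndim != 3:
            raise ValueError("bands must be a (n_bands, rows, cols) array")
        if len(self.band_names) != self.bands.shape[0]:
            raise ValueError(
                f"{len(self.band_names)} band names for "
                f"{self.bands.shape[0]} bands"
            )
        if self.kind not in ("reflectance", "dn"):
            raise ValueError(f"unknown scene kind {self.kind!r}")

    @property
    def shape(self) -> tuple[int, int]:
        """(rows, cols) of the raster grid."""
        return self.bands.shape[1:]

    @property
    def n_bands(self) -> int:
        return self.bands.shape[0]

    def band(self, name: str) -> np.ndarray:
        """Return the 2-D raster of a named band."""
        try:
            idx = self.band_names.index(name)
        except ValueError:
            raise KeyError(
                f"band {name!r} not in scene bands {self.band_names}"
            ) from None
        return self.bands[idx]
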