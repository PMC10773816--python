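"""Empirical line method (ELM) radiometric calibration.

Converts raw digital numbers (DN) to surface reflectance with a per-band
affine model fitted on diffuse calibration panels of known reflectance:

    reflectance_i = DN_i * gain_i + offset_i

with (gain, offset) per band estimated by ordinary least squares.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass

import numpy as np

from .scene import MultispectralScene
from .synthetic import PanelObservation

log = logging.getLogger(__name__)


class CalibrationError(ValueError):
    """ELM cannot be fitted or applied."""


@dataclass(frozen=True)
class BandCalibration:
    gain: float
    offset: float
    r_squared: float
    n_panels: int


@dataclass
class ElmCalibration:
    """Per-band affine DN -> reflectance calibration."""

    bands: dict[str, BandCalibration]

    def to_json(self) -> str:
        return json.dumps(
            {
                b: {
                    "gain": c.gain,
                    "offset": c.offset,
                    "r_squared": c.r_squared,
                    "n_panels": c.n_panels,
                }
                for b, c in self.bands.items()
            },
            indent=2,
        )

    @classmethod
    def from_json(cls, text: str) -> "ElmCalibration":
        raw = json.loads(text)
        return cls(
            bands={
                b: BandCalibration(
                    gain=v["gain"],
                    offset=v["offset"],
                    r_squared=v["r_squared"],
                    n_panels=v["n_panels"],
                )
                for b, v in raw.items()
            }
        )


def fit_elm(observations: list[PanelObservation]) -> ElmCalibration:
    """Fit per-band (gain, offset) by OLS on panel (DN, reflectance) pairs."""
    by_band: dict[str, list[PanelObservation]] = {}
    for o in observations:
        if not (np.isfinite(o.dn) and np.isfinite(o.reflectance)):
            raise CalibrationError(f"non-finite panel observation in band {o.band}")
        by_band.setdefault(o.band, []).append(o)

    bands = {}
    for band, obs in by_band.items():
        dn = np.array([o.dn for o in obs])
        refl = np.array([o.reflectance for o in obs])
        if len(np.unique(dn)) < 2:
            raise CalibrationError(
                f"band {band}: need >= 2 panels with distinct DN values"
            )
        design = np.column_stack([dn, np.ones_like(dn)])
        (gain, offset), *_ = np.linalg.lstsq(design, refl, rcond=None)
        fitted = gain * dn + offset
        ss_res = float(((refl - fitted) ** 2).sum())
        ss_tot = float(((refl - refl.mean()) ** 2).sum())
        r2 = 1.0 if ss_tot == 0 else max(0.0, 1.0 - ss_res / ss_tot)
        bands[band] = BandCalibration(
            gain=float(gain), offset=float(offset), r_squared=r2, n_panels=len(obs)
        )
    if not bands:
        raise CalibrationError("no panel observations")
    return ElmCalibration(bands=bands)


def apply_elm(
    scene_dn: MultispectralScene,
    calibration: ElmCalibration,
    clip: bool = True,
) -> MultispectralScene:
    """Transform a DN scene to reflectance per band.

    Negative / above-one reflectances are clipped to [0, 1] by default;
    the number of clipped pixels is logged.
    """
    missing = [b for b in scene_dn.band_names if b not in calibration.bands]
    if missing:
        raise CalibrationError(f"calibration missing band(s): {missing}")
    out = np.empty_like(scene_dn.bands, dtype=np.float64)
    for k, band in enumerate(scene_dn.band_names):
        cal = calibration.bands[band]
        out[k] = scene_dn.bands[k] * cal.gain + cal.offset
    if clip:
        n_clipped = int(np.count_nonzero((out < 0.0) | (out > 1.0)))
        if n_clipped:
            log.info("apply_elm: clipped %d pixel values to [0, 1]", n_clipped)
        np.clip(out, 0.0, 1.0, out=out)
    return MultispectralScene(
        bands=out,
        band_names=scene_dn.band_names,
        gsd_cm=scene_dn.gsd_cm,
        kind="reflectance",
        meta=dict(scene_dn.meta),
    )


def to_digital_numbers(
    scene: MultispectralScene,
    gains_per_band: dict[str, float],
    offsets_per_band: dict[str, float],
) -> MultispectralScene:
    """Invert the ELM: reflectance scene -> DN scene with known gain/offset.

    Used to emulate an uncalibrated sensor product from a generated
    reflectance scene (DN = (R - offset) / gain per band).
    """
    out = np.empty_like(scene.bands, dtype=np.float64)
    for k, band in enumerate(scene.band_names):
        gain = gains_per_band[band]
        if gain == 0:
            raise CalibrationError(f"band {band}: zero gain")
        out[k] = (scene.bands[k].astype(np.float64) - offsets_per_band[band]) / gain
    return MultispectralScene(
        bands=out,
        band_names=scene.band_names,
        gsd_cm=scene.gsd_cm,
        kind="dn",
        meta=dict(scene.meta),
    )
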