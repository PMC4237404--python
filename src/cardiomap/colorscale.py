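"""Voltage color scales: rendering polar maps to RGB and converting back.

The acquisition consoles render voltage polar maps with a fixed color coding
(red = lowest voltage / scar, yellow-green = intermediate, blue-violet =
normal).  To analyse exported raster images, the RGB values must be converted
back to voltages.  This module defines the package's own documented scales as
ordered ``(voltage_mV, (r, g, b))`` control points, renders with linear RGB
interpolation between control points, and inverts by nearest-point projection
onto the densely sampled color polyline.  Pixels farther than ``tol`` (RGB
Euclidean) from every scale color -- annotation overlays, background -- are
marked invalid rather than guessed.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.spatial import cKDTree

from .errors import ConfigurationError
from .noga import PolarMap

__all__ = [
    "BIPOLAR_SCALE",
    "UNIPOLAR_SCALE",
    "voltage_to_rgb",
    "rgb_to_voltage",
    "render_polar_png",
    "read_polar_png",
]

#: bipolar scale: red below the transmural cut-off, yellow-green through the
#: non-transmural band, blue-violet for normal tissue
BIPOLAR_SCALE = (
    (0.0, (255, 0, 0)),
    (0.8, (255, 200, 0)),
    (1.9, (0, 190, 0)),
    (3.5, (0, 60, 255)),
    (6.0, (170, 0, 255)),
)

#: unipolar scale: red infarct core, yellow-green border zone, blue-violet normal
UNIPOLAR_SCALE = (
    (0.0, (255, 0, 0)),
    (5.0, (255, 200, 0)),
    (15.0, (0, 190, 0)),
    (20.0, (0, 60, 255)),
    (30.0, (170, 0, 255)),
)

_SCALE_BY_KIND = {"bipolar_mV": BIPOLAR_SCALE, "unipolar_mV": UNIPOLAR_SCALE}
#: color of pixels carrying no data (outside the disk / invalid cells)
_BACKGROUND = (255, 255, 255)


def _check_scale(scale):
    volts = [v for v, _ in scale]
    if len(volts) < 2 or sorted(volts) != volts or len(set(volts)) != len(volts):
        raise ConfigurationError("color scale needs strictly increasing voltages")


def voltage_to_rgb(values, scale=BIPOLAR_SCALE) -> np.ndarray:
    """Map voltages to uint8 RGB by linear interpolation along the scale."""
    _check_scale(scale)
    volts = np.array([v for v, _ in scale], dtype=float)
    cols = np.array([c for _, c in scale], dtype=float)
    v = np.clip(np.asarray(values, dtype=float), volts[0], volts[-1])
    rgb = np.stack([np.interp(v, volts, cols[:, i]) for i in range(3)], axis=-1)
    return np.round(rgb).astype(np.uint8)


def rgb_to_voltage(image: np.ndarray, scale=BIPOLAR_SCALE, *,
                   tol: float = 30.0, samples_per_segment: int = 256):
    """Convert an RGB raster back to voltages.

    Each pixel snaps to the nearest point of the densely sampled color
    polyline and receives that point's voltage (linear interpolation between
    control points).  Returns ``(voltages, valid)``; pixels whose RGB distance
    to the polyline exceeds ``tol`` are invalid.
    """
    _check_scale(scale)
    img = np.asarray(image, dtype=float)
    if img.ndim != 3 or img.shape[-1] < 3:
        raise ConfigurationError("expected an (H, W, 3) RGB image")
    img = img[..., :3]

    volts, cols = [], []
    for (v0, c0), (v1, c1) in zip(scale[:-1], scale[1:]):
        f = np.linspace(0.0, 1.0, samples_per_segment, endpoint=False)
        volts.append(v0 + f * (v1 - v0))
        cols.append(np.asarray(c0, dtype=float)[None, :]
                    + f[:, None] * (np.asarray(c1, dtype=float) - np.asarray(c0, dtype=float)))
    volts.append(np.array([scale[-1][0]]))
    cols.append(np.asarray(scale[-1][1], dtype=float)[None, :])
    volts = np.concatenate(volts)
    cols = np.concatenate(cols)

    dist, idx = cKDTree(cols).query(img.reshape(-1, 3))
    values = volts[idx].reshape(img.shape[:2])
    valid = (dist <= tol).reshape(img.shape[:2])
    values = np.where(valid, values, np.nan)
    return values, valid


def render_polar_png(pmap: PolarMap, path, *, size: int = 200,
                     smooth_sigma: float = 0.0, scale=None) -> None:
    """Write a bull's-eye PNG plus a JSON sidecar describing the color scale.

    Invalid pixels render as white (outside the scale gamut, so a round trip
    marks them invalid again).  The sidecar ``<path>.json`` records the map
    kind and the control points, which :func:`read_polar_png` uses.
    """
    scale = scale if scale is not None else _SCALE_BY_KIND.get(pmap.kind)
    if scale is None:
        raise ConfigurationError(f"no default color scale for kind {pmap.kind!r}")
    raster, mask = pmap.to_raster(size=size, smooth_sigma=smooth_sigma)
    rgb = voltage_to_rgb(np.where(mask, raster, 0.0), scale)
    rgb[~mask] = _BACKGROUND
    Image.fromarray(rgb, mode="RGB").save(path)
    sidecar = {
        "kind": pmap.kind,
        "control_points": [[float(v), list(map(int, c))] for v, c in scale],
    }
    Path(str(path) + ".json").write_text(json.dumps(sidecar, indent=2))


def read_polar_png(path, *, tol: float = 30.0):
    """Read a rendered polar PNG back into a voltage raster via its sidecar.

    Returns ``(values, valid, kind)``.
    """
    sidecar = json.loads(Path(str(path) + ".json").read_text())
    scale = tuple((v, tuple(c)) for v, c in sidecar["control_points"])
    img = np.asarray(Image.open(path).convert("RGB"))
    values, valid = rgb_to_voltage(img, scale, tol=tol)
    return values, valid, sidecar["kind"]
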