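"""Shared grid and bull's-eye geometry helpers.

The left ventricle is discretised on an ``(n_slices, n_sectors)`` shell grid:
slice 0 is the apex, slice ``n_slices - 1`` the base; sector 0 starts at the
reference angle (right-ventricular insertion, the +x axis) and sectors run
counter-clockwise.  On the bull's-eye disk the apex sits at the centre and the
base at the rim, so a cell ``(s, k)`` maps to polar coordinates
``r = (s + 0.5) / n_slices`` and ``theta = (k + 0.5) * 2*pi / n_sectors``.
"""

from __future__ import annotations

import numpy as np

#: default analysis grid: 8 apico-basal slices x 32 wall sectors per slice
N_SLICES = 8
N_SECTORS = 32


def nearest_index(x):
    """Round to the nearest integer, halves away from the origin upward.

    Used everywhere a continuous coordinate is mapped onto the voxel lattice so
    that boundaries placed on half-integers resolve deterministically.
    """
    return np.floor(np.asarray(x) + 0.5).astype(int)


def segment12_labels(n_slices: int, n_sectors: int) -> np.ndarray:
    """Partition the grid into the 12-segment scheme (3 levels x 4 quadrants).

    Levels split the apico-basal slices into apical/mid/basal thirds and the
    sectors into four quadrants, giving labels ``level * 4 + quadrant`` in
    ``0..11``.  Every segment is non-empty for any grid with at least 3 slices
    and 4 sectors.
    """
    if n_slices < 3 or n_sectors < 4:
        raise ValueError("12-segment labelling needs >= 3 slices and >= 4 sectors")
    level = np.empty(n_slices, dtype=int)
    for i, idx in enumerate(np.array_split(np.arange(n_slices), 3)):
        level[idx] = i
    quadrant = (np.arange(n_sectors) * 4) // n_sectors
    return level[:, None] * 4 + quadrant[None, :]


def cell_polar_radius(slice_idx, n_slices: int):
    """Bull's-eye radial coordinate in (0, 1) of a slice ring centre."""
    return (np.asarray(slice_idx, dtype=float) + 0.5) / n_slices


def cell_angle(sector_idx, n_sectors: int):
    """Angle (rad) of a sector centre, measured from the sector-0 reference."""
    return (np.asarray(sector_idx, dtype=float) + 0.5) * (2.0 * np.pi / n_sectors)


def surface_xyz(slice_frac, theta, r_endo_mm: float, apex_to_base_mm: float):
    """Endocardial-surface coordinates (mm) of points on the shell.

    The endocardium is modelled as a cylinder of radius ``r_endo_mm`` whose
    long axis runs from the apex (z = 0) to the base
    (z = ``apex_to_base_mm``); ``slice_frac`` in [0, 1] is the normalised
    apico-basal position.
    """
    slice_frac = np.asarray(slice_frac, dtype=float)
    theta = np.asarray(theta, dtype=float)
    x = r_endo_mm * np.cos(theta)
    y = r_endo_mm * np.sin(theta)
    z = slice_frac * apex_to_base_mm
    return np.stack(np.broadcast_arrays(x, y, z), axis=-1)


def raster_coordinates(size: int):
    """Polar coordinates (r in [0, ...], theta in [0, 2pi)) per raster pixel.

    Pixels are centred; r = 1 is the rim of the inscribed disk.
    """
    c = (size - 1) / 2.0
    yy, xx = np.mgrid[0:size, 0:size]
    r = np.hypot(xx - c, yy - c) / c
    theta = np.mod(np.arctan2(yy - c, xx - c), 2.0 * np.pi)
    return r, theta


def grid_to_raster(values: np.ndarray, valid: np.ndarray, size: int = 200,
                   smooth_sigma: float = 0.0):
    """Interpolate an (n_slices, n_sectors) grid onto a bull's-eye raster.

    Bilinear in (slice, sector) with periodic wrap in sector and clamping in
    slice; invalid cells and pixels outside the disk come back as NaN with a
    False mask.  Optional Gaussian smoothing (normalised convolution, so the
    invalid mask does not bleed zeros into the picture) is for display only --
    all quantitative area work stays on the raw grid.
    """
    from scipy.ndimage import gaussian_filter

    values = np.asarray(values, dtype=float)
    valid = np.asarray(valid, dtype=bool)
    n_slices, n_sectors = values.shape
    r, theta = raster_coordinates(size)
    inside = r <= 1.0

    sf = np.clip(r * n_slices - 0.5, 0.0, n_slices - 1.0)
    s0 = np.floor(sf).astype(int)
    s1 = np.minimum(s0 + 1, n_slices - 1)
    ws = sf - s0

    kf = theta / (2.0 * np.pi) * n_sectors - 0.5
    k0 = np.floor(kf).astype(int) % n_sectors
    k1 = (k0 + 1) % n_sectors
    wk = np.mod(kf, 1.0)

    filled = np.where(valid, values, 0.0)
    vmask = valid.astype(float)

    def _bilin(grid):
        return ((1 - ws) * (1 - wk) * grid[s0, k0]
                + (1 - ws) * wk * grid[s0, k1]
                + ws * (1 - wk) * grid[s1, k0]
                + ws * wk * grid[s1, k1])

    num = _bilin(filled)
    den = _bilin(vmask)
    mask = inside & (den > 0.5)
    raster = np.full((size, size), np.nan)
    with np.errstate(invalid="ignore", divide="ignore"):
        raster[mask] = (num / den)[mask]

    if smooth_sigma > 0:
        w = np.where(mask, 1.0, 0.0)
        sm = gaussian_filter(np.where(mask, raster, 0.0), smooth_sigma)
        norm = gaussian_filter(w, smooth_sigma)
        with np.errstate(invalid="ignore", divide="ignore"):
            raster = np.where(mask, sm / norm, np.nan)
    return raster, mask


def connected_on_shell(support: np.ndarray) -> bool:
    """True if the True cells form one 4-connected region (sector axis wraps).

    An empty support counts as connected.
    """
    support = np.asarray(support, dtype=bool)
    n_slices, n_sectors = support.shape
    seeds = np.argwhere(support)
    if seeds.size == 0:
        return True
    seen = np.zeros_like(support)
    stack = [tuple(seeds[0])]
    seen[tuple(seeds[0])] = True
    while stack:
        s, k = stack.pop()
        for ds, dk in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            s2, k2 = s + ds, (k + dk) % n_sectors
            if 0 <= s2 < n_slices and support[s2, k2] and not seen[s2, k2]:
                seen[s2, k2] = True
                stack.append((s2, k2))
    return bool(np.array_equal(seen, support))
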