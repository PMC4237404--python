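"""Synthetic left-ventricle infarct phantoms and their two imaging renderings.

The phantom is a shell-coordinate model of the LV myocardium: an
``(n_slices, n_sectors)`` grid (apex at slice 0) carrying a wall thickness and
a ground-truth scar *transmurality* field -- the fraction of the wall depth,
measured from the endocardium outward, occupied by infarcted tissue.  Both
imaging modalities in this package are rendered from the same phantom:

* :func:`render_mri_stack` voxelises the shell into short-axis
  signal-intensity slices with a hyperintense scar (late-enhancement-like),
* :func:`sample_noga_points` draws sparse endocardial mapping points whose
  unipolar/bipolar voltages fall with local scar burden.

The voltage model is piecewise linear in transmurality and anchored so that
the classical bipolar viability cut-offs are the exact noise-free truth:
bipv(0.75) = 0.8 mV (transmural boundary) and bipv(0.25) = 1.9 mV
(non-transmural boundary).  Calibration routines downstream therefore have a
known recoverable answer.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from . import geometry
from .errors import ConfigurationError

__all__ = [
    "LVPhantom",
    "VoltageModel",
    "SliceStack",
    "make_phantom",
    "render_mri_stack",
    "sample_noga_points",
    "dense_sample_points",
]

#: default endocardial radius of the cylindrical shell (mm)
R_ENDO_MM = 20.0
#: default short-axis slice thickness (mm)
SLICE_THICKNESS_MM = 8.0
#: lowest transmurality assigned to scar-rim cells; keeps every scar cell
#: detectable at millimetre voxels (0.15 x 10 mm wall = 1.5 mm scar depth)
RIM_TRANSMURALITY = 0.15

POINT_COLUMNS = [
    "slice_idx", "sector_idx", "slice_frac", "theta_rad",
    "x_mm", "y_mm", "z_mm", "upv_mV", "bipv_mV", "stable",
]


# ---------------------------------------------------------------------------
# ground truth

@dataclass(frozen=True)
class LVPhantom:
    """Ground-truth myocardial shell with a scar-transmurality field."""

    n_slices: int
    n_sectors: int
    wall_thickness_mm: np.ndarray      # (n_slices, n_sectors)
    transmurality_field: np.ndarray    # (n_slices, n_sectors), values in [0, 1]
    segment12_labels: np.ndarray       # (n_slices, n_sectors), ints 0..11
    seed: int
    slice_thickness_mm: float = SLICE_THICKNESS_MM
    r_endo_mm: float = R_ENDO_MM

    def __post_init__(self):
        t = np.asarray(self.transmurality_field, dtype=float)
        if t.shape != (self.n_slices, self.n_sectors):
            raise ConfigurationError("transmurality field shape mismatch")
        if np.any(t < 0) or np.any(t > 1):
            raise ConfigurationError("transmurality values must lie in [0, 1]")
        labels = np.asarray(self.segment12_labels)
        if sorted(np.unique(labels)) != list(range(12)):
            raise ConfigurationError("segment labels must cover exactly 12 groups")
        if not geometry.connected_on_shell(t > 0):
            raise ConfigurationError("scar support must be a single connected region")

    # -- derived quantities -------------------------------------------------
    @property
    def n_cells(self) -> int:
        return self.n_slices * self.n_sectors

    @property
    def scar_support(self) -> np.ndarray:
        return self.transmurality_field > 0

    @property
    def apex_to_base_mm(self) -> float:
        return self.n_slices * self.slice_thickness_mm

    def infarct_surface_fraction(self) -> float:
        """Fraction of the endocardial surface over scar (cells are equal-area)."""
        return float(self.scar_support.mean())

    def surface_fraction_above(self, level: float) -> float:
        """Fraction of surface cells with transmurality strictly above ``level``."""
        return float((self.transmurality_field > level).mean())

    def analytic_scar_volume_fraction(self) -> float:
        """Scar volume as a fraction of myocardial volume, integrated exactly.

        Each cell is an annular wedge from the endocardial radius ``r`` out to
        ``r + w``; scar occupies the inner ``T * w`` of it, so its volume is
        proportional to ``(r + T*w)^2 - r^2``.
        """
        r = self.r_endo_mm
        w = np.asarray(self.wall_thickness_mm, dtype=float)
        t = self.transmurality_field
        scar = (r + t * w) ** 2 - r ** 2
        myo = (r + w) ** 2 - r ** 2
        return float(scar.sum() / myo.sum())


def make_phantom(infarct_fraction: float = 0.35, core_fraction: float = 0.40,
                 n_slices: int = geometry.N_SLICES,
                 n_sectors: int = geometry.N_SECTORS, *,
                 wall_thickness_mm: float = 10.0, seed: int = 0) -> LVPhantom:
    """Generate an LV phantom with a smooth anteroapical infarct.

    Parameters
    ----------
    infarct_fraction
        Fraction of the LV surface (grid cells) covered by scar, in [0, 1).
    core_fraction
        Fraction of the scar support with transmurality > 0.75 (the
        transmural "infarct core"), in [0, 1].
    wall_thickness_mm
        Uniform wall thickness of the shell.
    seed
        Seeds the infarct location/shape jitter; same arguments + seed give
        bit-identical phantoms.

    The infarct is an elliptical patch in (slice, sector) space centred
    anteroapically; within it, transmurality decays monotonically from a peak
    (0.85-0.95) at the centre through 0.75 at the core rim down to
    ``RIM_TRANSMURALITY`` at the outer rim.  Cell counts for the support and
    the core honour the requested fractions to the nearest cell.
    """
    if n_slices <= 0 or n_sectors <= 0:
        raise ConfigurationError("grid dimensions must be positive")
    if not 0.0 <= infarct_fraction < 1.0:
        raise ConfigurationError("infarct_fraction must lie in [0, 1)")
    if not 0.0 <= core_fraction <= 1.0:
        raise ConfigurationError("core_fraction must lie in [0, 1]")
    if wall_thickness_mm <= 0:
        raise ConfigurationError("wall thickness must be positive")

    rng = np.random.default_rng(seed)
    n_cells = n_slices * n_sectors
    n_scar = int(round(infarct_fraction * n_cells))
    t = np.zeros((n_slices, n_sectors))

    if n_scar > 0:
        # anteroapical ellipse: centre in the apical third, anterior quadrant
        slice_c = n_slices * rng.uniform(0.10, 0.28)
        sector_c = n_sectors * rng.uniform(0.30, 0.45)
        sa = rng.uniform(0.9, 1.1)                      # apico-basal semi-axis scale
        sb = sa * rng.uniform(1.5, 2.2) * (n_sectors / (4.0 * n_slices))

        ss, kk = np.mgrid[0:n_slices, 0:n_sectors]
        dk = (kk - sector_c + n_sectors / 2.0) % n_sectors - n_sectors / 2.0
        d = np.hypot((ss - slice_c) / sa, dk / sb)
        d = d + rng.uniform(0.0, 1e-9, size=d.shape)    # deterministic tie-break

        order = np.argsort(d, axis=None)
        scar_flat = order[:n_scar]
        n_core = int(round(core_fraction * n_scar))
        t_max = rng.uniform(0.85, 0.95)
        u = (np.arange(n_scar) + 0.5) / n_scar
        u_c = n_core / n_scar
        prof = np.empty(n_scar)
        if n_core > 0:
            core = u < u_c
            prof[core] = t_max - (t_max - 0.75) * (u[core] / u_c)
        if n_core < n_scar:
            # rim: continue from 0.75 down to the rim floor with the initial
            # slope matched to the core ramp's cell density, so the
            # transmurality histogram has no pile-up at the transmural
            # boundary, then descend linearly to RIM_TRANSMURALITY
            rim = u >= u_c
            v = (u[rim] - u_c) / (1.0 - u_c)
            if n_core > 0:
                w = (u_c / (1.0 - u_c)) * (0.15 / (t_max - 0.75))
                w = float(np.clip(w, 0.05, 0.9))
            else:
                w = 0.25
            prof[rim] = np.interp(v, [0.0, w, 1.0],
                                  [0.75, 0.60, RIM_TRANSMURALITY])
        t.flat[scar_flat] = prof

    return LVPhantom(
        n_slices=n_slices, n_sectors=n_sectors,
        wall_thickness_mm=np.full((n_slices, n_sectors), float(wall_thickness_mm)),
        transmurality_field=t,
        segment12_labels=geometry.segment12_labels(n_slices, n_sectors),
        seed=int(seed),
    )


# ---------------------------------------------------------------------------
# voltage model

@dataclass(frozen=True)
class VoltageModel:
    """Maps local scar transmurality to unipolar/bipolar electrogram voltages.

    Bipolar voltage is piecewise linear through the two anchor points
    ``(T, mV)`` -- by default (0.25, 1.9) and (0.75, 0.8) -- extended linearly
    and clipped to ``[bipv_floor_mV, bipv_plateau_mV]``.  Unipolar voltage
    reflects the summated activity of the surrounding endocardium, so it is
    driven by the scar burden averaged over a square neighbourhood of
    ``neighborhood_cells`` grid cells (0 = strictly local):
    ``upv = upv_normal - upv_scar_slope * burden``, clipped below.

    Gaussian noise of SD ``noise_sd_mV`` is added independently to every
    sampled voltage by :func:`sample_noga_points`.
    """

    upv_normal_mV: float = 18.0
    upv_scar_slope_mV: float = 27.0
    bipv_anchor_points: tuple = ((0.25, 1.9), (0.75, 0.8))
    noise_sd_mV: float = 0.1
    neighborhood_cells: int = 1
    bipv_floor_mV: float = 0.05
    bipv_plateau_mV: float = 6.0
    upv_floor_mV: float = 0.05

    def __post_init__(self):
        (t0, v0), (t1, v1) = self.bipv_anchor_points
        if not (t1 > t0 and v1 < v0):
            raise ConfigurationError("bipolar anchors must be strictly decreasing in T")
        if self.noise_sd_mV < 0:
            raise ConfigurationError("noise SD must be non-negative")

    def bipv(self, transmurality):
        (t0, v0), (t1, v1) = self.bipv_anchor_points
        slope = (v1 - v0) / (t1 - t0)
        v = v0 + slope * (np.asarray(transmurality, dtype=float) - t0)
        return np.clip(v, self.bipv_floor_mV, self.bipv_plateau_mV)

    def upv(self, scar_burden):
        v = self.upv_normal_mV - self.upv_scar_slope_mV * np.asarray(scar_burden, dtype=float)
        return np.clip(v, self.upv_floor_mV, None)

    def scar_burden(self, transmurality_field: np.ndarray) -> np.ndarray:
        """Neighbourhood-averaged transmurality (wraps in sector, clamps in slice)."""
        r = int(self.neighborhood_cells)
        if r <= 0:
            return np.asarray(transmurality_field, dtype=float)
        return ndimage.uniform_filter(
            np.asarray(transmurality_field, dtype=float),
            size=2 * r + 1, mode=("nearest", "wrap"))


# ---------------------------------------------------------------------------
# MRI-like rendering

@dataclass
class SliceStack:
    """Voxelised short-axis signal-intensity stack with myocardium masks.

    ``voxels`` has shape (planes, rows, cols); ``voxel_mm`` gives the
    (plane thickness, row, col) spacing.  ``endo_mask`` is the region enclosed
    by the endocardial border (blood pool), ``epi_mask`` the region enclosed
    by the epicardial border, so the myocardium is ``epi & ~endo``.
    ``remote_mask`` marks normal-appearing reference myocardium.
    ``true_scar_mask`` (synthetic renders only) is the ground truth.
    """

    voxels: np.ndarray
    voxel_mm: tuple
    endo_mask: np.ndarray
    epi_mask: np.ndarray
    remote_mask: np.ndarray
    n_slices: int
    planes_per_slice: int = 1
    true_scar_mask: np.ndarray | None = None

    def __post_init__(self):
        if self.voxels.shape != self.endo_mask.shape or self.voxels.shape != self.epi_mask.shape:
            raise ConfigurationError("mask shapes must match the voxel array")
        myo = self.myocardium_mask
        if not myo.reshape(myo.shape[0], -1).any(axis=1).all():
            raise ConfigurationError("myocardium mask empty on at least one plane")
        if np.any(self.remote_mask & ~myo):
            raise ConfigurationError("remote region must lie inside the myocardium")

    @property
    def myocardium_mask(self) -> np.ndarray:
        return self.epi_mask & ~self.endo_mask

    @property
    def voxel_volume_ml(self) -> float:
        return float(np.prod(self.voxel_mm)) / 1000.0


def render_mri_stack(phantom: LVPhantom, voxel_mm: float = 1.0,
                     si_normal_mean: float = 100.0, si_normal_sd: float = 10.0,
                     si_scar_mean: float = 160.0, seed: int = 0, *,
                     margin_mm: float = 3.0, planes_per_slice: int = 1) -> SliceStack:
    """Voxelise the phantom into a late-enhancement-like slice stack.

    Myocardial voxels whose depth from the endocardium is below
    ``T * wall_thickness`` draw their intensity from N(si_scar_mean,
    si_normal_sd); the rest of the myocardium from N(si_normal_mean,
    si_normal_sd).  The defaults (100/10/160) comfortably satisfy the
    2SD-separability precondition ``si_scar_mean > si_normal_mean + 2 sd``.
    ``remote_mask`` contains myocardium in cells at least one cell away from
    any scar.
    """
    if voxel_mm <= 0:
        raise ConfigurationError("voxel size must be positive")
    if si_normal_sd < 0:
        raise ConfigurationError("intensity SD must be non-negative")
    if not si_scar_mean > si_normal_mean + 2 * si_normal_sd:
        raise ConfigurationError(
            "si_scar_mean must exceed si_normal_mean + 2*si_normal_sd "
            "for the 2SD rule to be satisfiable")
    if planes_per_slice < 1:
        raise ConfigurationError("planes_per_slice must be >= 1")

    rng = np.random.default_rng(seed)
    wall = np.asarray(phantom.wall_thickness_mm, dtype=float)
    t_field = phantom.transmurality_field
    n_slices, n_sectors = t_field.shape
    r_endo = phantom.r_endo_mm

    # even grid with the LV axis on a voxel corner: wall radii then fall on
    # voxel edges along the axes, so boundary quantisation is symmetric
    half = r_endo + wall.max() + margin_mm
    n = 2 * int(np.ceil(half / voxel_mm))
    c = (n - 1) / 2.0
    yy, xx = (np.mgrid[0:n, 0:n] - c) * voxel_mm
    rho = np.hypot(xx, yy)
    theta = np.mod(np.arctan2(yy, xx), 2.0 * np.pi)
    sector = np.minimum((theta / (2.0 * np.pi) * n_sectors).astype(int), n_sectors - 1)

    # grid cells safely away from scar (for the remote reference region)
    support = t_field > 0
    padded = np.pad(support, ((1, 1), (0, 0)), mode="edge")
    padded = np.concatenate([padded[:, -1:], padded, padded[:, :1]], axis=1)
    near_scar = ndimage.binary_dilation(padded, structure=np.ones((3, 3), bool))
    safe_cell = ~near_scar[1:-1, 1:-1]

    n_planes = n_slices * planes_per_slice
    voxels = np.empty((n_planes, n, n))
    endo = np.empty((n_planes, n, n), dtype=bool)
    epi = np.empty_like(endo)
    remote = np.empty_like(endo)
    scar_true = np.empty_like(endo)

    for p in range(n_planes):
        s = p // planes_per_slice
        w = wall[s][sector]
        endo[p] = rho < r_endo
        epi[p] = rho < r_endo + w
        myo = epi[p] & ~endo[p]
        depth = rho - r_endo
        scar_true[p] = myo & (depth < t_field[s][sector] * w) & (t_field[s][sector] > 0)
        remote[p] = myo & safe_cell[s][sector]
        mean_map = np.where(scar_true[p], si_scar_mean, si_normal_mean)
        voxels[p] = np.where(myo, mean_map + si_normal_sd * rng.standard_normal((n, n)), 0.0)

    return SliceStack(
        voxels=voxels,
        voxel_mm=(phantom.slice_thickness_mm / planes_per_slice, voxel_mm, voxel_mm),
        endo_mask=endo, epi_mask=epi, remote_mask=remote,
        n_slices=n_slices, planes_per_slice=planes_per_slice,
        true_scar_mask=scar_true,
    )


# ---------------------------------------------------------------------------
# NOGA-like sparse sampling

def sample_noga_points(phantom: LVPhantom, model: VoltageModel | None = None,
                       n_points: int = 202, min_per_segment: int = 4,
                       seed: int = 0) -> pd.DataFrame:
    """Draw sparse endocardial mapping points with voltages from the model.

    At least ``min_per_segment`` points land in each of the 12 myocardial
    segments (sampled without replacement within the segment where possible);
    the remainder are uniform over the shell.  Each point carries endocardial
    surface coordinates (mm), bull's-eye coordinates, and unipolar/bipolar
    voltages evaluated at its grid cell plus independent Gaussian noise.
    """
    model = model or VoltageModel()
    if n_points < 12 * min_per_segment:
        raise ConfigurationError(
            f"n_points={n_points} cannot place {min_per_segment} points "
            "in each of 12 segments")

    rng = np.random.default_rng(seed)
    labels = phantom.segment12_labels
    flat_cells = np.arange(phantom.n_cells)

    chosen = []
    for seg in range(12):
        cells = flat_cells[labels.ravel() == seg]
        chosen.append(rng.choice(cells, size=min_per_segment,
                                 replace=len(cells) < min_per_segment))
    n_rest = n_points - 12 * min_per_segment
    if n_rest:
        chosen.append(rng.choice(flat_cells, size=n_rest, replace=True))
    cells = np.concatenate(chosen)
    s_idx, k_idx = np.divmod(cells, phantom.n_sectors)

    u = rng.uniform(0.0, 1.0, size=n_points)
    v = rng.uniform(0.0, 1.0, size=n_points)
    slice_frac = (s_idx + u) / phantom.n_slices
    theta = (k_idx + v) * (2.0 * np.pi / phantom.n_sectors)
    xyz = geometry.surface_xyz(slice_frac, theta, phantom.r_endo_mm,
                               phantom.apex_to_base_mm)

    burden = model.scar_burden(phantom.transmurality_field)
    upv = model.upv(burden[s_idx, k_idx])
    bipv = model.bipv(phantom.transmurality_field[s_idx, k_idx])
    if model.noise_sd_mV > 0:
        upv = upv + model.noise_sd_mV * rng.standard_normal(n_points)
        bipv = bipv + model.noise_sd_mV * rng.standard_normal(n_points)
    upv = np.clip(upv, model.upv_floor_mV, None)
    bipv = np.clip(bipv, model.bipv_floor_mV, None)

    return pd.DataFrame({
        "slice_idx": s_idx, "sector_idx": k_idx,
        "slice_frac": slice_frac, "theta_rad": theta,
        "x_mm": xyz[:, 0], "y_mm": xyz[:, 1], "z_mm": xyz[:, 2],
        "upv_mV": upv, "bipv_mV": bipv,
        "stable": np.ones(n_points, dtype=bool),
    })[POINT_COLUMNS]


def dense_sample_points(phantom: LVPhantom, model: VoltageModel | None = None,
                        noise_sd_mV: float = 0.0, seed: int = 0) -> pd.DataFrame:
    """One mapping point at the centre of every grid cell.

    The dense, noise-free limit of :func:`sample_noga_points`: with
    ``noise_sd_mV = 0`` the voltages equal the model evaluated on the grid
    exactly, which makes this the reference input for calibration and
    consistency checks.
    """
    model = model or VoltageModel()
    rng = np.random.default_rng(seed)
    s_idx, k_idx = np.divmod(np.arange(phantom.n_cells), phantom.n_sectors)
    slice_frac = (s_idx + 0.5) / phantom.n_slices
    theta = (k_idx + 0.5) * (2.0 * np.pi / phantom.n_sectors)
    xyz = geometry.surface_xyz(slice_frac, theta, phantom.r_endo_mm,
                               phantom.apex_to_base_mm)
    burden = model.scar_burden(phantom.transmurality_field)
    upv = model.upv(burden[s_idx, k_idx])
    bipv = model.bipv(phantom.transmurality_field[s_idx, k_idx])
    if noise_sd_mV > 0:
        upv = np.clip(upv + noise_sd_mV * rng.standard_normal(upv.size),
                      model.upv_floor_mV, None)
        bipv = np.clip(bipv + noise_sd_mV * rng.standard_normal(bipv.size),
                       model.bipv_floor_mV, None)
    return pd.DataFrame({
        "slice_idx": s_idx, "sector_idx": k_idx,
        "slice_frac": slice_frac, "theta_rad": theta,
        "x_mm": xyz[:, 0], "y_mm": xyz[:, 1], "z_mm": xyz[:, 2],
        "upv_mV": upv, "bipv_mV": bipv,
        "stable": np.ones(phantom.n_cells, dtype=bool),
    })[POINT_COLUMNS]
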