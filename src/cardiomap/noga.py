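"""Electroanatomical (NOGA-style) voltage polar maps.

Sparse endocardial mapping points are interpolated onto the shared
``(n_slices, n_sectors)`` bull's-eye grid by inverse-distance weighting within
the point-connection reach (15 mm by default, the distance below which points
are connected on the acquisition system).  The resulting unipolar (UPV) and
bipolar (BiPV) maps are classified with the standard viability thresholds --
UPV: > 15 mV normal, 5-15 mV border zone, < 5 mV infarct; BiPV: > 1.9 mV
normal, 0.8-1.9 mV non-transmural, < 0.8 mV transmural scar -- and the bipolar
thresholds can be re-derived from MRI transmurality maps by an iterative
100-step sweep or from unipolar viability labels by ROC analysis.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist
from sklearn.metrics import auc as _auc
from sklearn.metrics import roc_curve as _roc_curve

from . import geometry
from .errors import ConfigurationError, EmptyMapError, UndefinedStatisticError
from .mri import LE_MIN_TRANSMURALITY
from .phantom import R_ENDO_MM, SLICE_THICKNESS_MM

__all__ = [
    "PolarMap",
    "VoltageThresholds",
    "UNIPOLAR_THRESHOLDS",
    "BIPOLAR_THRESHOLDS",
    "ClassifiedVoltageMap",
    "SweepResult",
    "ROCResult",
    "MappingPoint",
    "build_polar_map",
    "classify_voltage",
    "threshold_sweep",
    "roc_bipv_cutoff",
]


class MappingPoint(tuple):
    """One endocardial sample: (x_mm, y_mm, z_mm, upv_mV, bipv_mV, stable)."""

    __slots__ = ()

    def __new__(cls, x_mm, y_mm, z_mm, upv_mV, bipv_mV, stable=True):
        if upv_mV < 0 or bipv_mV < 0:
            raise ConfigurationError("voltages must be non-negative")
        return super().__new__(cls, (x_mm, y_mm, z_mm, upv_mV, bipv_mV, bool(stable)))


@dataclass(frozen=True)
class PolarMap:
    """Scalar bull's-eye map on the shared (n_slices, n_sectors) grid.

    ``kind`` is one of ``unipolar_mV``, ``bipolar_mV``, ``class_label`` or
    ``transmurality``.  ``valid`` excludes the basal fibrous-ring annulus and
    cells beyond the interpolation reach of any accepted point.
    """

    values: np.ndarray
    valid: np.ndarray
    kind: str

    @property
    def n_slices(self) -> int:
        return self.values.shape[0]

    @property
    def n_sectors(self) -> int:
        return self.values.shape[1]

    def to_raster(self, size: int = 200, smooth_sigma: float = 2.0):
        return geometry.grid_to_raster(self.values, self.valid, size, smooth_sigma)


def build_polar_map(points: pd.DataFrame, field: str = "bipv",
                    connect_mm: float = 15.0,
                    n_slices: int = geometry.N_SLICES,
                    n_sectors: int = geometry.N_SECTORS, *,
                    fibrous_ring_frac: float = 0.08,
                    idw_power: float = 2.0,
                    r_endo_mm: float = R_ENDO_MM,
                    slice_thickness_mm: float = SLICE_THICKNESS_MM) -> PolarMap:
    """Interpolate accepted mapping points onto the bull's-eye grid.

    Only points flagged ``stable`` participate.  A grid cell receives the
    inverse-distance-weighted (power ``idw_power``) average of the voltages of
    all points strictly within ``connect_mm`` of its endocardial-surface
    position; cells with no point in reach are invalid, as is the outer
    fibrous-ring annulus (``fibrous_ring_frac`` of the bull's-eye radius, the
    non-contractile valve zone; set to 0 for inputs without that artifact).

    ``field`` selects ``"upv"`` or ``"bipv"`` (the ``*_mV`` column names are
    also accepted).
    """
    field = {"upv": "upv_mV", "bipv": "bipv_mV"}.get(field, field)
    if field not in ("upv_mV", "bipv_mV"):
        raise ConfigurationError(f"unknown field {field!r}")
    if connect_mm <= 0:
        raise ConfigurationError("connect_mm must be positive")
    if not 0.0 <= fibrous_ring_frac < 1.0:
        raise ConfigurationError("fibrous_ring_frac must lie in [0, 1)")

    pts = points[points["stable"].astype(bool)]
    if len(pts) == 0:
        raise EmptyMapError("no stable mapping points")
    if (pts[field] < 0).any():
        raise ConfigurationError("voltages must be non-negative")

    s_idx, k_idx = np.divmod(np.arange(n_slices * n_sectors), n_sectors)
    cell_xyz = geometry.surface_xyz(
        geometry.cell_polar_radius(s_idx, n_slices),
        geometry.cell_angle(k_idx, n_sectors),
        r_endo_mm, n_slices * slice_thickness_mm)
    pt_xyz = pts[["x_mm", "y_mm", "z_mm"]].to_numpy(dtype=float)

    d = cdist(cell_xyz, pt_xyz)
    reach = d < connect_mm
    w = np.where(reach, 1.0 / np.maximum(d, 1e-9) ** idw_power, 0.0)
    wsum = w.sum(axis=1)
    covered = reach.any(axis=1)
    vals = np.zeros(len(cell_xyz))
    vals[covered] = (w[covered] @ pts[field].to_numpy(dtype=float)) / wsum[covered]

    valid = covered.reshape(n_slices, n_sectors)
    if fibrous_ring_frac > 0:
        ring = geometry.cell_polar_radius(np.arange(n_slices), n_slices) \
            > 1.0 - fibrous_ring_frac
        valid = valid & ~ring[:, None]
    return PolarMap(values=vals.reshape(n_slices, n_sectors), valid=valid,
                    kind={"upv_mV": "unipolar_mV", "bipv_mV": "bipolar_mV"}[field])


# ---------------------------------------------------------------------------
# classification

@dataclass(frozen=True)
class VoltageThresholds:
    """Three-band voltage thresholds for one modality.

    Values strictly below ``low`` are the most severe class, values in
    ``[low, high]`` the intermediate class (boundary values belong to the
    middle band, honouring the printed strict inequalities), values strictly
    above ``high`` are normal.
    """

    modality: str  # "unipolar_mV" | "bipolar_mV"
    low: float
    high: float
    class_names: tuple  # (normal, intermediate, severe)

    def __post_init__(self):
        if not 0 < self.low < self.high:
            raise ConfigurationError("thresholds must be strictly ordered")

    def classify(self, values: np.ndarray) -> np.ndarray:
        v = np.asarray(values, dtype=float)
        return np.where(v < self.low, 2, np.where(v <= self.high, 1, 0))


UNIPOLAR_THRESHOLDS = VoltageThresholds(
    "unipolar_mV", 5.0, 15.0, ("normal", "border", "infarct"))
BIPOLAR_THRESHOLDS = VoltageThresholds(
    "bipolar_mV", 0.8, 1.9, ("normal", "non_transmural", "transmural"))


@dataclass(frozen=True)
class ClassifiedVoltageMap:
    labels: np.ndarray
    valid: np.ndarray
    thresholds: VoltageThresholds
    area_fractions: dict  # class name -> % of valid cells


def classify_voltage(pmap: PolarMap,
                     thresholds: VoltageThresholds) -> ClassifiedVoltageMap:
    """Three-class labelling of a voltage map with area fractions.

    Area fractions are percentages of the valid LV surface and sum to 100%.
    """
    if pmap.kind != thresholds.modality:
        raise ConfigurationError(
            f"map kind {pmap.kind!r} does not match thresholds for "
            f"{thresholds.modality!r}")
    labels = thresholds.classify(pmap.values)
    n_valid = int(pmap.valid.sum())
    if n_valid == 0:
        raise EmptyMapError("no valid cells to classify")
    fractions = {
        name: float(100.0 * ((labels == code) & pmap.valid).sum() / n_valid)
        for code, name in ((0, thresholds.class_names[0]),
                           (1, thresholds.class_names[1]),
                           (2, thresholds.class_names[2]))
    }
    return ClassifiedVoltageMap(labels=labels, valid=pmap.valid.copy(),
                                thresholds=thresholds, area_fractions=fractions)


# ---------------------------------------------------------------------------
# threshold calibration against MRI transmurality

@dataclass(frozen=True)
class SweepResult:
    """Outcome of the iterative bipolar-threshold calibration.

    ``correlation[level]`` is the Pearson r, across subjects, between the
    bipolar low-voltage area under each candidate threshold and the MRI area
    above that transmurality level; ``best_cutoff_mV[level]`` maximises it.
    ``saturated[level]`` flags a maximum on the sweep boundary (the true
    optimum lies at or beyond the edge of the swept range).
    """

    thresholds_mV: np.ndarray
    levels: tuple
    correlation: dict
    best_cutoff_mV: dict
    saturated: dict
    noga_areas: np.ndarray  # (n_subjects, n_thresholds), % of cropped area
    mri_areas: np.ndarray   # (n_subjects, n_levels)


def threshold_sweep(bipolar_maps: list, trans_maps: list,
                    crop_masks: list | None = None, *,
                    lo: float = 0.5, hi: float = 1.5, steps: int = 100,
                    levels: tuple = (25, 30, 50, 60, 75),
                    mode: str = "areas") -> SweepResult:
    """Calibrate bipolar cut-offs by an iterative threshold sweep.

    For every candidate threshold ``t`` (``steps`` values from ``lo`` to
    ``hi``) the bipolar region ``{BiPV < t}`` is measured inside each
    subject's crop region (by default the MRI late-enhancement infarct area)
    and correlated with the MRI region above each transmurality level; the
    threshold maximising the correlation is reported per level.

    Two correlation targets are available:

    ``mode="areas"`` (default)
        Per-subject areas (% of the crop) are correlated across the cohort --
        the method-comparison statistic reported for cohorts.

    ``mode="cells"``
        The binary indicators are correlated over all cropped cells pooled
        across subjects (a phi coefficient).  This variant weighs every cell's
        agreement directly, which keeps the optimum pinned to the underlying
        voltage boundary when measurement noise perturbs per-subject areas,
        and is therefore the variant used for cut-off calibration.
    """
    if not bipolar_maps or len(bipolar_maps) != len(trans_maps):
        raise ConfigurationError("need equally many bipolar and transmurality maps")
    if crop_masks is not None and len(crop_masks) != len(bipolar_maps):
        raise ConfigurationError("crop mask count mismatch")
    if mode not in ("areas", "cells"):
        raise ConfigurationError("mode must be 'areas' or 'cells'")

    thresholds = np.linspace(lo, hi, steps)
    n_subj = len(bipolar_maps)
    noga_areas = np.empty((n_subj, steps))
    mri_areas = np.empty((n_subj, len(levels)))
    pooled_b, pooled_t = [], []
    for i, (bmap, tmap) in enumerate(zip(bipolar_maps, trans_maps)):
        if bmap.values.shape != tmap.values.shape:
            raise ConfigurationError("maps must share the grid")
        crop = (crop_masks[i] if crop_masks is not None
                else tmap.values > LE_MIN_TRANSMURALITY)
        m = bmap.valid & tmap.valid & crop
        if not m.any():
            raise ConfigurationError(f"empty crop region for subject {i}")
        bv = bmap.values[m]
        noga_areas[i] = 100.0 * (bv[None, :] < thresholds[:, None]).mean(axis=1)
        mri_areas[i] = [100.0 * (tmap.values[m] * 100.0 > lev).mean()
                        for lev in levels]
        pooled_b.append(bv)
        pooled_t.append(tmap.values[m])

    if np.allclose(noga_areas.std(axis=0), 0.0) and n_subj > 1:
        raise UndefinedStatisticError(
            "bipolar areas are constant across the cohort at every threshold; "
            "correlation is undefined")

    if mode == "cells":
        bv = np.concatenate(pooled_b)
        tv = np.concatenate(pooled_t)
        x = (bv[None, :] < thresholds[:, None]).astype(float)  # (steps, cells)
        xc = x - x.mean(axis=1, keepdims=True)
        x_sd = x.std(axis=1)
    na = noga_areas - noga_areas.mean(axis=0)
    na_sd = na.std(axis=0)

    correlation, best, saturated = {}, {}, {}
    for j, lev in enumerate(levels):
        if mode == "cells":
            y = (tv * 100.0 > lev).astype(float)
            yc = y - y.mean()
            y_sd = y.std()
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (xc @ yc) / (len(y) * x_sd * y_sd)
            r[x_sd == 0] = np.nan
            degenerate = y_sd == 0
        else:
            ma = mri_areas[:, j] - mri_areas[:, j].mean()
            ma_sd = ma.std()
            with np.errstate(invalid="ignore", divide="ignore"):
                r = (na * ma[:, None]).mean(axis=0) / (na_sd * ma_sd)
            r[na_sd == 0] = np.nan
            degenerate = ma_sd == 0
        if degenerate or np.all(np.isnan(r)):
            correlation[lev] = np.full(steps, np.nan)
            best[lev] = np.nan
            saturated[lev] = True
            continue
        k = int(np.nanargmax(r))
        correlation[lev] = r
        best[lev] = float(thresholds[k])
        saturated[lev] = k in (0, steps - 1)
    return SweepResult(thresholds_mV=thresholds, levels=tuple(levels),
                       correlation=correlation, best_cutoff_mV=best,
                       saturated=saturated, noga_areas=noga_areas,
                       mri_areas=mri_areas)


# ---------------------------------------------------------------------------
# ROC derivation of bipolar cut-offs from unipolar viability

@dataclass(frozen=True)
class ROCResult:
    auc: float
    auc_ci95: tuple
    fpr: np.ndarray
    tpr: np.ndarray
    table: pd.DataFrame  # cutoff_mV, sensitivity, specificity
    n_positive: int
    n_negative: int


def roc_bipv_cutoff(points: pd.DataFrame, upv_nonviable_cutoff: float = 5.0,
                    *, n_bootstrap: int = 2000, seed: int = 0) -> ROCResult:
    """ROC of bipolar voltage against unipolar-defined non-viability.

    Points with UPV < ``upv_nonviable_cutoff`` are the positive (non-viable)
    class; lower bipolar voltage scores as more likely non-viable.  AUC uses
    the trapezoidal rule; the 95% CI is a seeded nonparametric bootstrap
    (percentile method, ``n_bootstrap`` resamples).  The table lists
    sensitivity and specificity at every candidate bipolar cut-off, where a
    point is called non-viable when BiPV < cut-off.
    """
    pts = points[points["stable"].astype(bool)]
    y = (pts["upv_mV"].to_numpy(dtype=float) < upv_nonviable_cutoff).astype(int)
    score = -pts["bipv_mV"].to_numpy(dtype=float)
    n_pos, n_neg = int(y.sum()), int((1 - y).sum())
    if n_pos == 0 or n_neg == 0:
        raise UndefinedStatisticError(
            "ROC undefined: both viability classes must be present")

    fpr, tpr, thr = _roc_curve(y, score)
    roc_auc = float(_auc(fpr, tpr))

    rng = np.random.default_rng(seed)
    boots = []
    n = len(y)
    for _ in range(n_bootstrap):
        idx = rng.integers(0, n, n)
        yb = y[idx]
        if yb.min() == yb.max():
            continue
        fb, tb, _ = _roc_curve(yb, score[idx])
        boots.append(_auc(fb, tb))
    ci = (float(np.percentile(boots, 2.5)), float(np.percentile(boots, 97.5))) \
        if boots else (np.nan, np.nan)

    table = pd.DataFrame({
        "cutoff_mV": -thr,           # BiPV < cutoff called non-viable
        "sensitivity": tpr,
        "specificity": 1.0 - fpr,
    })
    return ROCResult(auc=roc_auc, auc_ci95=ci, fpr=fpr, tpr=tpr, table=table,
                     n_positive=n_pos, n_negative=n_neg)
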