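"""Agreement statistics between voltage-map and MRI-derived measurements.

* Overlap ratio ``(c + d) / (a + b)`` between two region maps -- equal to the
  Dice coefficient ``2|A∩B| / (|A| + |B|)`` when both maps live on one grid --
  graded good (> 60%), moderate (50-60%) or poor.
* Pearson product-moment correlation with the conventional magnitude grading
  (> 0.5 large, 0.3-0.5 moderate, 0.1-0.3 small).
* Least-absolute-residual (L1) robust linear regression by iteratively
  reweighted least squares.
* Bland-Altman bias analysis with limits of agreement at exactly +/- 2 SD.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass

import numpy as np
from scipy import stats

from .errors import ConfigurationError, ConvergenceError, UndefinedStatisticError
from .mri import TransmuralityPolarMap
from .noga import PolarMap

__all__ = [
    "OverlapResult",
    "PearsonResult",
    "RobustFitResult",
    "BlandAltmanResult",
    "AgreementReport",
    "REGION_DEFINITIONS",
    "overlap_ratio",
    "region_overlap",
    "pearson_with_grade",
    "robust_linear_fit",
    "bland_altman",
]

#: overlap grading: > 60% good accuracy, 50-60% moderate, below poor
OVERLAP_GOOD = 0.60
OVERLAP_MODERATE = 0.50


# ---------------------------------------------------------------------------
# overlap ratio

@dataclass(frozen=True)
class OverlapResult:
    a_pct: float      # MRI region area, % of valid surface
    b_pct: float      # voltage-map region area
    c_pct: float      # voltage-map shape overlaid on the MRI map, overlap area
    d_pct: float      # MRI shape overlaid on the voltage map, overlap area
    ratio: float      # (c + d) / (a + b)
    grade: str        # good | moderate | poor

    def as_dict(self):
        return asdict(self)


def _grade(ratio: float) -> str:
    if ratio > OVERLAP_GOOD:
        return "good"
    if ratio >= OVERLAP_MODERATE:
        return "moderate"
    return "poor"


def overlap_ratio(mri_mask: np.ndarray, noga_mask: np.ndarray,
                  valid: np.ndarray | None = None) -> OverlapResult:
    """Overlap ratio (c + d) / (a + b) of two boolean region masks.

    Both masks live on the shared grid, so each overlay area equals the
    intersection (c = d) and the ratio reduces to the Dice coefficient.
    Areas are percentages of the valid surface.  Raises when both regions are
    empty (a + b = 0, ratio undefined).
    """
    mri_mask = np.asarray(mri_mask, dtype=bool)
    noga_mask = np.asarray(noga_mask, dtype=bool)
    if mri_mask.shape != noga_mask.shape:
        raise ConfigurationError("masks must share the grid")
    if valid is None:
        valid = np.ones_like(mri_mask)
    valid = np.asarray(valid, dtype=bool)
    n_valid = int(valid.sum())
    if n_valid == 0:
        raise UndefinedStatisticError("no valid cells")

    a = int((mri_mask & valid).sum())
    b = int((noga_mask & valid).sum())
    inter = int((mri_mask & noga_mask & valid).sum())
    if a + b == 0:
        raise UndefinedStatisticError("both regions empty; overlap ratio undefined")
    ratio = 2.0 * inter / (a + b)
    to_pct = 100.0 / n_valid
    return OverlapResult(a_pct=a * to_pct, b_pct=b * to_pct,
                         c_pct=inter * to_pct, d_pct=inter * to_pct,
                         ratio=ratio, grade=_grade(ratio))


#: region definitions pairing a bipolar-voltage band (mV) with an MRI
#: transmurality band (fraction): transmural scar, non-transmural scar and the
#: combined (not-normal) infarct.  Half-open voltage/transmurality bands keep
#: transmural + non_transmural == combined exactly.
REGION_DEFINITIONS = {
    "transmural": {"bipv": (None, 0.8), "trans": (0.75, None)},
    "non_transmural": {"bipv": (0.8, 1.9), "trans": (0.25, 0.75)},
    "combined": {"bipv": (None, 1.9), "trans": (0.25, None)},
}


def _band_mask(values, lo, hi):
    m = np.ones(values.shape, dtype=bool)
    if lo is not None:
        m &= values >= lo if hi is not None else values > lo
    if hi is not None:
        m &= values < hi
    return m


def region_overlap(trans_map: TransmuralityPolarMap, bipolar_map: PolarMap,
                   region: str = "transmural") -> OverlapResult:
    """Overlap ratio for one of the named infarct regions.

    ``transmural``: BiPV < 0.8 mV vs transmurality > 75%;
    ``non_transmural``: BiPV 0.8-1.9 mV vs transmurality 25-75%;
    ``combined``: BiPV < 1.9 mV vs transmurality > 25%.
    Only cells valid on both maps enter the comparison.
    """
    try:
        spec = REGION_DEFINITIONS[region]
    except KeyError:
        raise ConfigurationError(
            f"unknown region {region!r}; available: {sorted(REGION_DEFINITIONS)}"
        ) from None
    valid = trans_map.valid & bipolar_map.valid
    blo, bhi = spec["bipv"]
    tlo, thi = spec["trans"]
    bmask = _band_mask(bipolar_map.values, blo, bhi)
    # transmurality bands: value exactly on the lower edge belongs below
    t = trans_map.values
    tmask = t > tlo if tlo is not None else np.ones(t.shape, dtype=bool)
    if thi is not None:
        tmask &= t <= thi
    return overlap_ratio(tmask, bmask, valid)


# ---------------------------------------------------------------------------
# correlation / regression / Bland-Altman

@dataclass(frozen=True)
class PearsonResult:
    r: float
    p: float
    n: int
    grade: str  # large | moderate | small | negligible

    def as_dict(self):
        return asdict(self)


def pearson_with_grade(x, y) -> PearsonResult:
    """Pearson product-moment correlation with the conventional grading.

    |r| > 0.5 is a large correlation, 0.3-0.5 moderate, 0.1-0.3 small,
    below 0.1 negligible.  Two-sided p via the t transform.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("x and y must be equal-length vectors")
    if len(x) < 3:
        raise UndefinedStatisticError("need at least 3 pairs")
    if x.std() == 0 or y.std() == 0:
        raise UndefinedStatisticError("correlation undefined for zero variance")
    res = stats.pearsonr(x, y)
    r = float(res.statistic)
    mag = abs(r)
    grade = ("large" if mag > 0.5 else
             "moderate" if mag > 0.3 else
             "small" if mag > 0.1 else "negligible")
    return PearsonResult(r=r, p=float(res.pvalue), n=len(x), grade=grade)


@dataclass(frozen=True)
class RobustFitResult:
    slope: float
    intercept: float
    n_iter: int
    max_abs_change: float

    def as_dict(self):
        return asdict(self)


def robust_linear_fit(x, y, *, max_iter: int = 200, tol: float = 1e-10,
                      eps: float = 1e-8) -> RobustFitResult:
    """Least-absolute-residual straight line by IRLS.

    Minimises ``sum |y - (a x + b)|`` with iteratively reweighted least
    squares: weights ``1 / max(|residual|, eps)``, starting from the ordinary
    least-squares line, stopping when both parameters change by less than
    ``tol``.  Raises :class:`ConvergenceError` with diagnostics if the
    iteration cap is hit.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("x and y must be equal-length vectors")
    if len(x) < 2:
        raise UndefinedStatisticError("need at least 2 points")
    if np.ptp(x) == 0:
        raise UndefinedStatisticError("slope undefined for constant x")

    A = np.column_stack([x, np.ones_like(x)])
    beta = np.linalg.lstsq(A, y, rcond=None)[0]
    obj = float(np.abs(y - A @ beta).sum())
    change = np.inf
    for it in range(1, max_iter + 1):
        r = y - A @ beta
        w = 1.0 / np.maximum(np.abs(r), eps)
        Aw = A * w[:, None]
        beta_new = np.linalg.solve(A.T @ Aw, Aw.T @ y)
        change = float(np.max(np.abs(beta_new - beta)))
        obj_new = float(np.abs(y - A @ beta_new).sum())
        # the eps weight floor limits attainable parameter resolution to
        # order eps: near the optimum the iterates dither at that scale, so
        # stop on parameter stagnation (absolute, or at the eps floor) or on
        # objective stagnation
        converged = (change < tol or change < 100.0 * eps
                     or abs(obj - obj_new) < tol * (1.0 + obj))
        beta, obj = beta_new, obj_new
        if converged:
            return RobustFitResult(slope=float(beta[0]), intercept=float(beta[1]),
                                   n_iter=it, max_abs_change=change)
    raise ConvergenceError(
        f"L1 regression did not converge in {max_iter} iterations "
        f"(last change {change:.3e}, slope {beta[0]:.6g}, intercept {beta[1]:.6g})")


@dataclass(frozen=True)
class BlandAltmanResult:
    """Bias analysis of paired measurements; differences are (first - second).

    ``limits`` are exactly ``mean_diff +/- 2 * sd_diff``; ``half_width`` is
    the 2 SD half-width of the limits, reported alongside the SD itself.
    """

    mean_diff: float
    sd_diff: float
    lower_limit: float
    upper_limit: float
    half_width: float
    n: int

    def as_dict(self):
        return asdict(self)


def bland_altman(x, y) -> BlandAltmanResult:
    """Bland-Altman statistics of paired differences ``x - y``.

    Call as ``bland_altman(noga, mri)`` to follow the convention that a
    positive mean difference means the voltage map overestimates the MRI
    measurement.  SD uses the n-1 denominator; limits are mean +/- 2 SD.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ConfigurationError("paired vectors must have equal length")
    if len(x) < 2:
        raise UndefinedStatisticError("need at least 2 pairs")
    d = x - y
    mean = float(d.mean())
    sd = float(d.std(ddof=1))
    return BlandAltmanResult(mean_diff=mean, sd_diff=sd,
                             lower_limit=mean - 2.0 * sd,
                             upper_limit=mean + 2.0 * sd,
                             half_width=2.0 * sd, n=len(d))


# ---------------------------------------------------------------------------
# aggregate report

@dataclass
class AgreementReport:
    """Agreement between the two modalities for one cohort (or one subject).

    ``overlaps`` maps region name -> :class:`OverlapResult` summaries;
    ``pearson``, ``robust_fit`` and ``bland_altman`` map comparison name ->
    the corresponding result objects.
    """

    overlaps: dict
    pearson: dict
    robust_fit: dict
    bland_altman: dict

    def as_dict(self):
        return {
            "overlaps": {k: v.as_dict() if hasattr(v, "as_dict") else v
                         for k, v in self.overlaps.items()},
            "pearson": {k: v.as_dict() for k, v in self.pearson.items()},
            "robust_fit": {k: v.as_dict() for k, v in self.robust_fit.items()},
            "bland_altman": {k: v.as_dict() for k, v in self.bland_altman.items()},
        }
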