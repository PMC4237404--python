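"""Cohort orchestration: generate N phantoms, run both pipelines, compare.

A :class:`CohortConfig` (one YAML file) drives a full reproducible
experiment: the master seed spawns one child seed per subject, each subject
is rendered through the MRI and voltage pipelines, per-subject areas and
overlap ratios are tabulated, and cohort-level statistics (Pearson, robust
regression, Bland-Altman, threshold-sweep calibration, ROC) are collected
into an :class:`CohortResult`.  Identical config + seed give byte-identical
CSV outputs.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__, compare, mri, noga, phantom
from .errors import CardiomapError, ConfigurationError, UndefinedStatisticError

__all__ = ["CohortConfig", "CohortResult", "SubjectResult", "run_cohort"]

log = logging.getLogger("cardiomap")

#: cohort comparison pairs: name -> (voltage-map column, MRI column)
COMPARISONS = {
    "infarct_size": ("noga_upv_total_pct", "mri_le_area_pct"),
    "transmural": ("noga_bipv_transmural_pct", "mri_transmural_pct"),
    "non_transmural": ("noga_bipv_non_transmural_pct", "mri_non_transmural_pct"),
}


@dataclass(frozen=True)
class CohortConfig:
    """Parameters of one synthetic cohort experiment.

    Phantom parameters are drawn uniformly from the given ranges per subject.
    ``noise_free=True`` switches off the voltage noise, the image noise and
    the unipolar neighbourhood summation, making every measurement an exact
    function of the ground truth (the configuration used by the
    self-consistency checks).
    """

    n_subjects: int = 60
    infarct_fraction_range: tuple = (0.25, 0.45)
    core_fraction_range: tuple = (0.25, 0.55)
    n_slices: int = 8
    n_sectors: int = 32
    wall_thickness_mm: float = 10.0
    # MRI rendering
    voxel_mm: float = 1.0
    si_normal_mean: float = 100.0
    si_normal_sd: float = 10.0
    si_scar_mean: float = 160.0
    si_scheme: str = "25-50-75"
    # voltage sampling
    n_points: int = 202
    min_per_segment: int = 4
    voltage_noise_sd_mV: float = 0.1
    upv_neighborhood_cells: int = 1
    connect_mm: float = 15.0
    # phantoms carry no valve-plane low-voltage artifact, so nothing is
    # excluded at the basal rim by default
    fibrous_ring_frac: float = 0.0
    # calibration sweep
    run_sweep: bool = True
    sweep_lo: float = 0.5
    sweep_hi: float = 1.5
    sweep_steps: int = 100
    sweep_levels: tuple = (25, 30, 50, 60, 75)
    sweep_mode: str = "cells"   # pooled-cell correlation for calibration
    noise_free: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.n_subjects < 1:
            raise ConfigurationError("n_subjects must be >= 1")
        for name in ("infarct_fraction_range", "core_fraction_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi <= 1) or (name.startswith("infarct") and hi >= 1):
                raise ConfigurationError(f"{name} must satisfy 0 <= lo <= hi (< 1)")
        if self.si_scheme not in mri.SCHEMES:
            raise ConfigurationError(f"unknown SI scheme {self.si_scheme!r}")
        if self.sweep_mode not in ("areas", "cells"):
            raise ConfigurationError("sweep_mode must be 'areas' or 'cells'")

    # -- serialisation ------------------------------------------------------
    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["infarct_fraction_range"] = list(d["infarct_fraction_range"])
        d["core_fraction_range"] = list(d["core_fraction_range"])
        d["sweep_levels"] = list(d["sweep_levels"])
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "CohortConfig":
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(d) - known
        if unknown:
            raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("infarct_fraction_range", "core_fraction_range", "sweep_levels"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    @classmethod
    def from_yaml(cls, path) -> "CohortConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()) or {})

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()).hexdigest()[:12]

    def voltage_model(self) -> phantom.VoltageModel:
        return phantom.VoltageModel(
            noise_sd_mV=0.0 if self.noise_free else self.voltage_noise_sd_mV,
            neighborhood_cells=0 if self.noise_free else self.upv_neighborhood_cells)


@dataclass
class SubjectResult:
    index: int
    seed: int
    row: dict
    trans_map: mri.TransmuralityPolarMap
    bipolar_map: noga.PolarMap
    unipolar_map: noga.PolarMap
    points: pd.DataFrame


@dataclass
class CohortResult:
    config: CohortConfig
    subjects: pd.DataFrame
    summary: pd.DataFrame
    report: dict
    agreement: compare.AgreementReport | None
    sweep: noga.SweepResult | None
    subject_results: list
    failures: list


def _subject_seeds(master_seed: int, n: int) -> list:
    children = np.random.SeedSequence(master_seed).spawn(n)
    return [int(c.generate_state(1)[0] % (2 ** 31)) for c in children]


def run_subject(config: CohortConfig, index: int, seed: int) -> SubjectResult:
    """Generate one phantom and run both pipelines on it."""
    rng = np.random.default_rng(seed)
    infarct_f = rng.uniform(*config.infarct_fraction_range)
    core_f = rng.uniform(*config.core_fraction_range)
    ph = phantom.make_phantom(infarct_f, core_f, config.n_slices, config.n_sectors,
                              wall_thickness_mm=config.wall_thickness_mm,
                              seed=seed)

    # MRI arm
    stack = phantom.render_mri_stack(
        ph, voxel_mm=config.voxel_mm, si_normal_mean=config.si_normal_mean,
        si_normal_sd=0.0 if config.noise_free else config.si_normal_sd,
        si_scar_mean=config.si_scar_mean, seed=seed + 1)
    scar = mri.segment_2sd(stack)
    vol = mri.infarct_volume(scar, stack)
    tmap = mri.transmurality_map(scar, stack, n_sectors=config.n_sectors)
    classified = mri.classify_transmurality(tmap, config.si_scheme)

    # voltage arm
    model = config.voltage_model()
    points = phantom.sample_noga_points(ph, model, n_points=config.n_points,
                                        min_per_segment=config.min_per_segment,
                                        seed=seed + 2)
    upv_map = noga.build_polar_map(points, "upv", config.connect_mm,
                                   config.n_slices, config.n_sectors,
                                   fibrous_ring_frac=config.fibrous_ring_frac)
    bipv_map = noga.build_polar_map(points, "bipv", config.connect_mm,
                                    config.n_slices, config.n_sectors,
                                    fibrous_ring_frac=config.fibrous_ring_frac)
    upv_cls = noga.classify_voltage(upv_map, noga.UNIPOLAR_THRESHOLDS)
    bipv_cls = noga.classify_voltage(bipv_map, noga.BIPOLAR_THRESHOLDS)

    row = {
        "subject": index, "seed": seed,
        "infarct_fraction": infarct_f, "core_fraction": core_f,
        "truth_surface_pct": 100.0 * ph.infarct_surface_fraction(),
        "truth_volume_pct": 100.0 * ph.analytic_scar_volume_fraction(),
        "mri_volume_ml": vol.ml,
        "mri_volume_pct": vol.percent_of_myocardium,
        "mri_le_area_pct": mri.le_area_fraction(tmap),
        "mri_transmural_pct": 100.0 * float(
            (tmap.values[tmap.valid] > 0.75).mean()),
        "mri_non_transmural_pct": 100.0 * float(
            ((tmap.values[tmap.valid] > 0.25)
             & (tmap.values[tmap.valid] <= 0.75)).mean()),
        "noga_upv_infarct_pct": upv_cls.area_fractions["infarct"],
        "noga_upv_border_pct": upv_cls.area_fractions["border"],
        "noga_upv_total_pct": (upv_cls.area_fractions["infarct"]
                               + upv_cls.area_fractions["border"]),
        "noga_bipv_transmural_pct": bipv_cls.area_fractions["transmural"],
        "noga_bipv_non_transmural_pct": bipv_cls.area_fractions["non_transmural"],
        "noga_bipv_total_pct": (bipv_cls.area_fractions["transmural"]
                                + bipv_cls.area_fractions["non_transmural"]),
    }
    for name, cls_name in (("transmural", "transmural"),
                           ("non_transmural", "non_transmural"),
                           ("combined", "combined")):
        try:
            row[f"overlap_{name}"] = compare.region_overlap(
                tmap, bipv_map, cls_name).ratio
        except UndefinedStatisticError:
            row[f"overlap_{name}"] = np.nan
    for cname, frac in classified.area_fractions.items():
        row[f"mri_scheme_{cname}_pct"] = frac

    return SubjectResult(index=index, seed=seed, row=row, trans_map=tmap,
                         bipolar_map=bipv_map, unipolar_map=upv_map,
                         points=points)


def run_cohort(config: CohortConfig, out_dir=None, *,
               write_maps: bool = False) -> CohortResult:
    """Run the full cohort experiment described by ``config``.

    A subject that fails is recorded in ``failures`` and the cohort
    continues.  If ``out_dir`` is given, per-subject tables, the cohort
    summary and a JSON report (with the package version, the config hash and
    every seed) are persisted there.
    """
    seeds = _subject_seeds(config.seed, config.n_subjects)
    results, failures, rows = [], [], []
    for i, seed in enumerate(seeds):
        try:
            res = run_subject(config, i, seed)
            results.append(res)
            rows.append(res.row)
        except CardiomapError as exc:  # noqa: PERF203 - per-subject fault isolation
            log.warning("subject %d failed: %s", i, exc)
            failures.append({"subject": i, "seed": seed, "error": str(exc)})
    if not rows:
        raise CardiomapError("every subject failed")
    subjects = pd.DataFrame(rows)

    # cohort-level agreement
    pearson, robust, bland = {}, {}, {}
    for name, (xcol, ycol) in COMPARISONS.items():
        x = subjects[xcol].to_numpy()
        y = subjects[ycol].to_numpy()
        try:
            pearson[name] = compare.pearson_with_grade(x, y)
            robust[name] = compare.robust_linear_fit(x, y)
            bland[name] = compare.bland_altman(x, y)
        except (UndefinedStatisticError, CardiomapError) as exc:
            log.warning("comparison %s undefined: %s", name, exc)
    overlap_summary = {}
    for region in ("transmural", "non_transmural", "combined"):
        vals = subjects[f"overlap_{region}"].dropna().to_numpy()
        overlap_summary[region] = {
            "mean": float(vals.mean()) if vals.size else float("nan"),
            "sd": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
            "n_undefined": int(subjects[f"overlap_{region}"].isna().sum()),
        }
    agreement = compare.AgreementReport(overlaps=overlap_summary, pearson=pearson,
                                        robust_fit=robust, bland_altman=bland)

    sweep = None
    if config.run_sweep and len(results) >= 3:
        try:
            sweep = noga.threshold_sweep(
                [r.bipolar_map for r in results],
                [r.trans_map for r in results],
                lo=config.sweep_lo, hi=config.sweep_hi,
                steps=config.sweep_steps, levels=config.sweep_levels,
                mode=config.sweep_mode)
        except (UndefinedStatisticError, ConfigurationError) as exc:
            log.warning("threshold sweep undefined: %s", exc)

    roc = None
    try:
        pooled = pd.concat([r.points for r in results], ignore_index=True)
        roc = noga.roc_bipv_cutoff(pooled, seed=config.seed)
    except UndefinedStatisticError as exc:
        log.warning("ROC undefined: %s", exc)

    summary = _summarise(subjects)
    report = {
        "package_version": __version__,
        "config": config.to_dict(),
        "config_hash": config.config_hash(),
        "subject_seeds": seeds,
        "n_completed": len(results),
        "failures": failures,
        "agreement": agreement.as_dict(),
        "sweep_best_cutoff_mV": (
            {str(k): v for k, v in sweep.best_cutoff_mV.items()} if sweep else None),
        "sweep_saturated": (
            {str(k): bool(v) for k, v in sweep.saturated.items()} if sweep else None),
        "roc_auc": roc.auc if roc else None,
        "roc_auc_ci95": list(roc.auc_ci95) if roc else None,
    }

    result = CohortResult(config=config, subjects=subjects, summary=summary,
                          report=report, agreement=agreement, sweep=sweep,
                          subject_results=results, failures=failures)
    if out_dir is not None:
        _persist(result, Path(out_dir), write_maps=write_maps)
    return result


def _summarise(subjects: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in subjects.columns if c not in ("subject", "seed")]
    means, sds = [], []
    for c in cols:
        vals = subjects[c].dropna().to_numpy(dtype=float)
        means.append(float(vals.mean()) if vals.size else float("nan"))
        sds.append(float(vals.std(ddof=1)) if vals.size > 1 else float("nan"))
    return pd.DataFrame({"metric": cols, "mean": means, "sd": sds})


def _persist(result: CohortResult, out_dir: Path, *, write_maps: bool) -> None:
    from . import io as cio
    from . import plotting

    out_dir.mkdir(parents=True, exist_ok=True)
    result.subjects.to_csv(out_dir / "subjects.csv", index=False)
    result.summary.to_csv(out_dir / "summary.csv", index=False)
    (out_dir / "report.json").write_text(json.dumps(result.report, indent=2))
    if result.sweep is not None:
        curve = pd.DataFrame({"threshold_mV": result.sweep.thresholds_mV})
        for lev in result.sweep.levels:
            curve[f"r_level_{lev}"] = result.sweep.correlation[lev]
        curve.to_csv(out_dir / "sweep_curve.csv", index=False)
    if write_maps:
        for res in result.subject_results:
            sub = out_dir / f"subject_{res.index:03d}"
            sub.mkdir(exist_ok=True)
            cio.write_points_csv(res.points, sub / "points.csv")
            cio.write_polar_map_csv(res.trans_map, sub / "transmurality_map.csv")
            cio.write_polar_map_csv(res.bipolar_map, sub / "bipolar_map.csv")
            cio.write_polar_map_csv(res.unipolar_map, sub / "unipolar_map.csv")
            plotting.bulls_eye(res.trans_map, sub / "transmurality.png",
                               title="cMRI transmurality")
            plotting.bulls_eye(res.bipolar_map, sub / "bipolar.png",
                               title="Bipolar voltage (mV)")
    log.info("cohort written to %s (config %s)", out_dir,
             result.config.config_hash())
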