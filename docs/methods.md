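# Methods

`cardiomap` quantifies how well catheter-based electroanatomical voltage
mapping agrees with late-gadolinium-enhancement (LE) cardiac MRI for
delineating myocardial infarct size and transmurality, the measurements that
guide targeted intramyocardial injection therapy.  Both modalities are
reduced to the same representation — a bull's-eye polar map of the left
ventricle (LV) with the apex at the centre, 8 apico-basal slice rings and 32
angular sectors per ring — and compared with overlap, correlation and bias
statistics.  Because matched voltage-map/MRI data sets are not publicly
deposited, the package ships a first-class synthetic phantom generator that
renders both modalities from one shared ground truth, which makes every
comparison exactly checkable.

## The phantom

The LV myocardium is modelled directly in shell coordinates: an
`(n_slices, n_sectors)` grid (default 8 × 32, apex at slice 0, sector 0 at
the right-ventricular insertion reference) carrying a wall thickness
(uniform 10 mm by default) and a ground-truth *transmurality* field
`T ∈ [0, 1]` — the fraction of wall depth, measured from the endocardium
outward, occupied by scar.  Every quantity the package compares lives on
this grid, so shell coordinates preserve all wall-depth structure while
avoiding 3-D meshing.  For physical distances the endocardium is treated as
a cylinder of radius 20 mm whose axis runs apex → base with 8-mm slice
spacing.

`make_phantom(infarct_fraction, core_fraction, …, seed)` places an
elliptical anteroapical scar (location and aspect jittered by the seed):

* the scar support occupies `infarct_fraction` of the surface cells and the
  transmural core (`T > 0.75`) occupies `core_fraction` of the support, both
  to the nearest cell (largest-distance-rank truncation);
* within the scar, `T` decreases monotonically with elliptical distance:
  linearly from a per-phantom peak `T_max ∈ [0.85, 0.95]` down to 0.75 at
  the core rim, then from 0.75 to a floor of 0.15 at the outer rim.  The
  first rim segment's slope is chosen so the cell density of `T` just below
  0.75 matches the density just above it.  This keeps the transmurality
  histogram smooth across the transmural/non-transmural boundary — there is
  no artificial pile-up of cells at the classification edge — which is what
  makes the bipolar cut-off identifiable by calibration (see below).  The
  0.15 floor guarantees every scar cell produces at least 1.5 mm of scar
  depth, i.e. is detectable at millimetre voxels.

Defaults `infarct_fraction = 0.35`, `core_fraction = 0.40` give a large
anteroapical infarct (~35 % of the endocardial surface, ~20 % of myocardial
volume), the scale of an extensive reperfused LAD infarct.

### MRI rendering

`render_mri_stack` voxelises each slice ring into a short-axis
signal-intensity image.  Myocardial voxels whose depth from the endocardium
is below `T·wall` draw from N(`si_scar_mean`, `si_normal_sd`), the rest from
N(`si_normal_mean`, `si_normal_sd`); defaults 160/100/10 (arbitrary units)
comfortably satisfy the separability precondition
`scar_mean > normal_mean + 2·sd`.  The voxel lattice is centred on a voxel
*corner*, not a voxel centre: wall radii then fall on voxel edges along the
axes and boundary quantisation is symmetric rather than biased by half a
voxel.  A `remote_mask` marks myocardium at least one grid cell away from
any scar, serving as the normal-appearing reference region.  The rendered
ground-truth scar mask travels with the stack (`true_scar_mask`) for
validation only.

### Voltage model and sparse sampling

Electrogram voltages are piecewise-linear functions of local scar burden,
anchored so that the classical bipolar viability cut-offs are the exact
noise-free truth:

* bipolar: the line through (T = 0.25, 1.9 mV) and (T = 0.75, 0.8 mV),
  extended linearly and clipped to [0.05, 6.0] mV.  On [0, 1] it is strictly
  decreasing with bipv(0) = 2.45 mV.
* unipolar: `upv = 18 − 27·S` mV clipped below at 0.05 mV, where `S` is the
  transmurality averaged over a square neighbourhood (radius 1 cell by
  default) — unipolar electrograms summate the activity of the surrounding
  endocardium.  Healthy tissue reads 18 mV (> 15 mV normal band); `S > 0.48`
  reads below the 5-mV non-viability cut-off.

`sample_noga_points` draws ~202 endocardial points (≥ 4 per segment of the
12-segment scheme: 3 apico-basal levels × 4 quadrants), evaluates the model
at each point's grid cell and adds independent Gaussian noise
(`noise_sd_mV`, default 0.1 mV).  `dense_sample_points` places one noise-free
point at every cell centre — the exact-sampling limit used by calibration
and consistency checks.  The "noise-free" configuration used throughout
testing means: voltage noise off, image noise off, *and* the unipolar
neighbourhood radius set to 0, so every measurement is a deterministic
function of the cell's own ground truth.

## MRI pipeline

**2SD segmentation.** A myocardial voxel is scar when its intensity strictly
exceeds mean + 2 sample standard deviations (n − 1) of the remote region.
With iid Gaussian noise this tags ~2.3 % of normal myocardium by
construction; at the default geometry that still yields Dice ≥ 0.95 against
the ground-truth mask.  A remote region smaller than 2 voxels is rejected; a
zero-variance region degenerates to thresholding at the mean (a uniform
stack gives an empty mask).

**Infarct volume** is voxel count × voxel volume, absolute (mL) and as % of
myocardial volume; the phantom's analytic annular-wedge integral
`((r+Tw)² − r²) / ((r+w)² − r²)` is the oracle.

**Transmurality map.** Per slice and sector, transmurality is the radial
scar extent projected on the wall midline divided by the wall thickness.
Two constructions are provided:

* `method="rank"` (default): per sector, myocardial voxels are ordered by
  radius from the myocardial centroid; the endocardial and epicardial edges
  are the midpoints of the radial gaps between blood pool and innermost wall
  voxel and between outermost wall voxel and the tissue beyond, and the scar
  front is the gap midpoint at the scar-voxel count's rank.  This sub-voxel
  gap inversion assumes scar grows from the endocardium outward (the LE
  infarct pattern); it recovers noise-free phantoms with max cell error
  ≤ 0.05 at 1-mm voxels (typically ≤ 0.04).
* `method="rays"`: explicit nearest-voxel ray casting (9 interior rays per
  sector, quarter-voxel steps), transmurality = scar-run / wall-run per ray,
  averaged.  Transparent, makes no contiguity assumption, and is exact on
  axis-aligned analytic sectors (full-thickness → 1.0, half-thickness → 0.5),
  but fully exposed to half-voxel boundary quantisation on oblique sectors.

Multi-plane slices aggregate with the mean by default (`aggregate="max"`
available); sectors without myocardium are invalid and excluded downstream.
A sector counts as "late-enhancing" when its measured transmurality exceeds
0.075 — halfway between the largest value a scar-free sector accrues through
voxelisation (≤ 0.05) and the smallest value a true rim produces (≥ 0.10).

**SI classification.** Two band schemes, with values exactly on an interior
edge assigned to honour the printed strict inequalities:
`25-50-75` = normal [0, 25), non-transmural [25, 50], border (50, 75],
transmural (75, 100]; `30-60` = normal [0, 30], non-transmural (30, 60],
transmural (60, 100].  The treatment of exactly 30 % is an interpretation
(the scheme is printed both as 0–30–60–100 and as 31–60 for the middle
band); the bands above tile [0, 100] without gaps.  Area fractions are % of
valid cells and sum to 100.

## Voltage pipeline

**Map construction.** Accepted (stable) points are interpolated onto the
grid by inverse-distance weighting (power 2) using 3-D endocardial-surface
distances, with reach equal to the 15-mm point-connection distance; cells
beyond every point's reach are invalid.  A configurable outer annulus
(default 8 % of the bull's-eye radius) models the fibrous-ring/valve zone
exclusion; the cohort runner sets it to 0 because phantoms carry no
valve-plane artifact.  Nearest-neighbour behaviour for a cell reached by a
single point is the IDW limit.

**Classification.** Unipolar: infarct < 5 mV, border [5, 15] mV, normal
> 15 mV.  Bipolar: transmural < 0.8 mV, non-transmural [0.8, 1.9] mV, normal
> 1.9 mV.  Boundary values land in the middle band, honouring the printed
strict inequalities on both sides.

**Threshold sweep.** The bipolar cut-off is re-derived against MRI
transmurality by testing 100 thresholds from 0.5 to 1.5 mV: per threshold
`t`, the bipolar region {BiPV < t} inside the crop (default: the LE infarct
area) is correlated with the MRI region {T > level} for levels 25/30/50/60/75 %,
and the maximising `t` is reported per level, with a saturation flag when
the maximum sits on the sweep boundary.  Two correlation targets are
implemented because the choice is genuinely open: `mode="areas"` correlates
per-subject areas across the cohort (the method-comparison statistic), and
`mode="cells"` correlates the binary indicators over all cropped cells
pooled across subjects (a phi coefficient).  On noise-free cohorts both
recover the anchors exactly (level 75 → 0.80 mV within one 0.01-mV step,
level 50 → 1.35 mV; levels 25/30 saturate at 1.5 mV since their anchors,
1.9 and 1.79 mV, lie outside the window).  Under measurement noise the
per-subject area statistic is unstable: misclassification noise concentrates
at the decision boundary and correlates with per-subject boundary-cell
density, so the argmax drifts along the nearly flat correlation ridge.  The
pooled-cell statistic weighs each cell's agreement directly and stays within
±0.03 mV of the anchor at 0.1-mV voltage noise; it is therefore the default
for calibration (`CohortConfig.sweep_mode = "cells"`), while the area curve
remains available for cohort reporting.

**ROC.** With unipolar < 5 mV defining non-viability, bipolar voltage is
scored (lower = more likely non-viable); AUC by the trapezoidal rule,
95 % CI by seeded nonparametric bootstrap (2000 resamples, percentile
method — the CI method is a package choice), and a
sensitivity/specificity table over all candidate cut-offs.

**Colour scales.** Maps render to RGB through documented control points
(red = scar → yellow-green → blue-violet = normal) with linear interpolation;
inversion snaps each pixel to the nearest point of the densely sampled
colour polyline and refuses pixels farther than 30 RGB units (annotations,
background), marking them invalid rather than guessing.  A JSON sidecar
carries the scale with every PNG, so rendering round-trips within half a
control-point spacing.

## Agreement statistics

* **Overlap ratio** `(c + d)/(a + b)` between an MRI region and a voltage
  region.  Both maps share one grid, so each overlay area equals the
  intersection (c = d) and the ratio reduces to the Dice coefficient — the
  shared-grid simplification is exact here because both maps are produced in
  the same coordinate frame.  Regions: transmural (BiPV < 0.8 vs T > 75 %),
  non-transmural (BiPV 0.8–1.9 vs T 25–75 %), combined (BiPV < 1.9 vs
  T > 25 %); the voltage/transmurality bands are half-open so transmural +
  non-transmural = combined exactly.  Grades: > 60 % good, 50–60 % moderate,
  else poor (conventional, configurable constants).  Empty region pairs
  (a + b = 0) raise rather than return a number.
* **Pearson correlation** with two-sided p (t transform) and the
  conventional magnitude grading: > 0.5 large, 0.3–0.5 moderate, 0.1–0.3
  small, else negligible.
* **Least-absolute-residual regression** by IRLS with weights
  `1/max(|r|, 1e-8)`, 200-iteration cap.  The 1e-8 weight floor limits
  attainable parameter resolution to about 1e-6, so iteration stops when
  parameter changes fall below 1e-10, below 100× the floor, or when the
  objective stagnates; true non-convergence raises with diagnostics.  The
  exact optimum (line through two data points, an LP vertex) is the test
  oracle.  Two points are fitted exactly.
* **Bland-Altman**: differences are (voltage map − MRI), so positive bias
  means the voltage map overestimates; SD uses n − 1; limits are exactly
  mean ± 2 SD, and both the SD and the 2-SD half-width are reported
  explicitly since conventions differ.

## Cohort runner

`CohortConfig` (one YAML file) fixes subject count, phantom parameter
ranges (`infarct_fraction` U(0.25, 0.45), `core_fraction` U(0.25, 0.55) by
default), noise levels, sweep settings and a master seed that spawns one
child seed per subject via `numpy.random.SeedSequence`.  `run_cohort`
isolates per-subject failures (recorded, cohort continues), tabulates
per-subject areas and overlaps, computes cohort Pearson/robust/Bland-Altman
for infarct size (unipolar total vs LE area), transmural and non-transmural
sizes, runs the calibration sweep and the pooled ROC, and persists
byte-identical CSV/JSON outputs (with package version, config hash and all
seeds) for a given config + seed.

## Problem sizes and what the tests show

The shipped checks run at the study grid (8 × 32 cells, 1-mm voxels, ~66²
pixels per slice) with cohorts of 30 subjects for calibration and 60 for
end-to-end consistency; the whole suite and the acceptance script each
complete in well under a minute on one CPU.  On noise-free cohorts the two
arms agree essentially exactly (r > 0.99, bias below one grid cell,
combined overlap > 0.95 per subject), which validates the bookkeeping, not
the biology.  What the phantom does **not** emulate: real LE texture
(partial-volume, heterogeneous core, microvascular obstruction), respiratory
/ registration misalignment between modalities, catheter sampling bias
toward reachable endocardium, fibrous-ring voltage artifacts, and
non-infarct low-voltage substrates.  Passing tests therefore demonstrate
correctness of the pipeline's constructions and statistics under a known
ground truth, with realistic noise showing graceful degradation — not
clinical accuracy on real animals or patients.

## Numerical conventions

Voxel-lattice lookups round half away from the origin upward
(`floor(x + 0.5)`), making half-integer boundaries deterministic.  Sector 0
starts at the reference angle (+x axis, the RV insertion); `sector_origin_deg`
rotates it.  Bull's-eye rasters are bilinear in (slice, sector) with
periodic wrap in sector; smoothing is display-only — every quantitative area
is computed on the raw 8 × 32 grid.  The 17-segment overlay familiar from
clinical displays is cosmetic and never used in computation.
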