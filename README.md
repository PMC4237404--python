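# cardiomap

Agreement analysis between catheter-based electroanatomical voltage mapping
and late-gadolinium-enhancement (LE) cardiac MRI for myocardial infarct size
and transmurality — the two imaging views used to steer intramyocardial
regenerative injection therapy.  Both modalities are reduced to the same
left-ventricular bull's-eye polar map (apex at the centre, 8 apico-basal
slices × 32 sectors) and compared quantitatively.  Because matched data sets
of this kind are not publicly deposited, the package includes a first-class
synthetic LV infarct phantom that renders *both* modalities from one shared
ground truth, so every statistic has a known correct answer.

**For:** researchers in cardiac electrophysiology / imaging who need a
tested, reproducible implementation of this comparison pipeline, and anyone
validating scar-segmentation or voltage-threshold calibration methods
against controllable ground truth.

## What it computes

* **Phantom** (`cardiomap.phantom`): shell-coordinate LV with an
  anteroapical scar of spatially varying transmurality `T` (fraction of wall
  depth infarcted); renders an MRI-like voxel stack (hyperintense scar,
  Gaussian noise) and sparse endocardial voltage points whose unipolar (UPV)
  and bipolar (BiPV) voltages fall with scar burden.  The bipolar model is
  anchored at (T = 0.75 → 0.8 mV) and (T = 0.25 → 1.9 mV), so the classical
  cut-offs are the exact noise-free truth.
* **MRI pipeline** (`cardiomap.mri`): "2SD" scar segmentation
  (SI > mean + 2 SD of remote myocardium), infarct volume (mL and % of LV
  myocardium), midline-projected 8 × 32 transmurality polar map, and SI
  classification under the 25/50/75 and 30/60 band schemes.
* **Voltage pipeline** (`cardiomap.noga`): inverse-distance interpolation of
  mapping points within the 15-mm connection reach, Table-style viability
  classification (UPV 5/15 mV, BiPV 0.8/1.9 mV), RGB ↔ voltage colour-scale
  conversion for raster maps, iterative 100-step bipolar threshold
  calibration against MRI transmurality, and ROC derivation of BiPV
  cut-offs from UPV-defined non-viability.
* **Agreement** (`cardiomap.compare`): overlap ratio (c + d)/(a + b) —
  the Dice coefficient on the shared grid — for transmural, non-transmural
  and combined infarct regions; Pearson correlation with conventional
  grading; least-absolute-residual (L1) regression; Bland-Altman bias with
  ±2 SD limits.
* **Cohorts** (`cardiomap.cohort`): one YAML config → N seeded phantoms →
  both pipelines → per-subject tables and cohort statistics, byte-identical
  under a fixed seed.

## Worked example

```python
import cardiomap as cm

ph = cm.make_phantom(infarct_fraction=0.35, core_fraction=0.40, seed=1)
stack = cm.render_mri_stack(ph, seed=2)                    # MRI arm
scar = cm.segment_2sd(stack)
tmap = cm.transmurality_map(scar, stack)
points = cm.sample_noga_points(ph, n_points=202, seed=3)   # voltage arm
bmap = cm.build_polar_map(points, "bipv", fibrous_ring_frac=0.0)
for region in ("transmural", "non_transmural", "combined"):
    r = cm.region_overlap(tmap, bmap, region)
    print(f"{region:>15}: MRI {r.a_pct:5.1f}%  NOGA {r.b_pct:5.1f}%  "
          f"overlap {100 * r.ratio:5.1f}% ({r.grade})")
```

prints (exactly, for these seeds):

```
     transmural: MRI  14.8%  NOGA  14.1%  overlap  97.3% (good)
 non_transmural: MRI  19.1%  NOGA  19.9%  overlap  94.0% (good)
       combined: MRI  34.0%  NOGA  34.0%  overlap  97.7% (good)
```

The transmural region is where BiPV < 0.8 mV on the voltage map and
measured transmurality > 75 % on the MRI map; the overlap percentage is the
Dice agreement of the two regions on the shared grid, graded good above
60 %.  The residual disagreement comes from image noise in the 2SD
segmentation and the interpolation halo of the 202-point sampling.  Running
`examples/05_cohort_experiment.py` repeats this over a 12-subject cohort and
adds correlations (r ≈ 0.88–0.98), Bland-Altman biases and the calibrated
bipolar cut-off (0.88 mV under realistic noise; 0.80 mV exactly when noise
is off, by construction of the voltage model).

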