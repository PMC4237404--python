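"""Generate an LV infarct phantom and render it into both modalities.

The phantom is the shared ground truth: a shell-coordinate myocardium with an
anteroapical scar whose transmurality (fraction of wall depth infarcted)
decays from a transmural core to the rim.  From it we render a
late-enhancement-like voxel stack and sample a sparse endocardial voltage map.
"""

import cardiomap as cm

ph = cm.make_phantom(infarct_fraction=0.35, core_fraction=0.40, seed=1)
print(f"phantom: {ph.n_slices} slices x {ph.n_sectors} sectors, "
      f"scar on {100 * ph.infarct_surface_fraction():.1f}% of the surface")
print(f"analytic scar volume: {100 * ph.analytic_scar_volume_fraction():.1f}% "
      "of the myocardium")

stack = cm.render_mri_stack(ph, voxel_mm=1.0, seed=2)
print(f"MRI stack: {stack.voxels.shape} voxels at {stack.voxel_mm} mm, "
      f"{int(stack.myocardium_mask.sum())} myocardial voxels")

points = cm.sample_noga_points(ph, n_points=202, min_per_segment=4, seed=3)
print(f"voltage map: {len(points)} endocardial points, "
      f"unipolar {points.upv_mV.min():.2f}-{points.upv_mV.max():.2f} mV, "
      f"bipolar {points.bipv_mV.min():.2f}-{points.bipv_mV.max():.2f} mV")
# low voltages sit over the scar: the same ground truth drives both modalities
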