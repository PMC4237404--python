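"""Late-enhancement analysis: 2SD segmentation, volume, transmurality map.

Scar voxels are those brighter than the remote myocardium's mean + 2 SD; the
segmented scar is projected radially per sector into an 8 x 32 bull's-eye
transmurality map and classified under the 25/50/75 signal-intensity scheme.
"""

import cardiomap as cm

ph = cm.make_phantom(seed=1)
stack = cm.render_mri_stack(ph, seed=2)

scar = cm.segment_2sd(stack)
vol = cm.infarct_volume(scar, stack)
print(f"infarct volume: {vol.ml:.1f} mL "
      f"({vol.percent_of_myocardium:.1f}% of LV myocardium)")

tmap = cm.transmurality_map(scar, stack)
print(f"LE area: {cm.le_area_fraction(tmap):.1f}% of the LV surface")

cls = cm.classify_transmurality(tmap, "25-50-75")
for name, pct in cls.area_fractions.items():
    print(f"  {name:>15}: {pct:5.1f}% of sectors")
# the four classes tile the surface: transmural (>75%), border (51-75%),
# non-transmural (25-50%) and normal (<25%) sum to 100%
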