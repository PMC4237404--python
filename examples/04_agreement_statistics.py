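"""Agreement between the two modalities for one subject.

Overlap ratio (c+d)/(a+b) -- the Dice coefficient on the shared grid -- for
the transmural, non-transmural and combined infarct regions, graded good
(> 60%) / moderate (50-60%) / poor.
"""

import cardiomap as cm

ph = cm.make_phantom(seed=5)
stack = cm.render_mri_stack(ph, seed=6)
tmap = cm.transmurality_map(cm.segment_2sd(stack), stack)
points = cm.sample_noga_points(ph, seed=7)
bmap = cm.build_polar_map(points, "bipv", fibrous_ring_frac=0.0)

for region in ("transmural", "non_transmural", "combined"):
    res = cm.region_overlap(tmap, bmap, region)
    print(f"{region:>15}: MRI {res.a_pct:5.1f}%  NOGA {res.b_pct:5.1f}%  "
          f"overlap {100 * res.ratio:5.1f}% ({res.grade})")
# both maps live on one grid, so the two overlay areas coincide and the ratio
# equals 2|A∩B| / (|A| + |B|)
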