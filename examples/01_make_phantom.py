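"""Generate a paired diagnostic/planning CT phantom and inspect it.

The bundle holds a dCT (curved diagnostic couch, pre-deformation anatomy), a
pCT (flat couch, anatomy displaced by a known smooth field), the ground-truth
deformation, and body/GTV/OAR masks in the planning frame.
"""

import numpy as np

from latticeplan import PhantomSpec, make_phantom, similarity_report

spec = PhantomSpec(region="thorax", grid_shape=(64, 64, 32), spacing=(4.0, 4.0, 5.0),
                   body_semiaxes_mm=(100.0, 69.0), body_z_halfextent_mm=75.0,
                   gtv_center_mm=(40.0, 8.0, 0.0), gtv_semiaxes_mm=(36.0, 31.0, 30.0),
                   seed=7)
b = make_phantom(spec)

print(f"dCT HU range: [{b.dct.voxels.min():.0f}, {b.dct.voxels.max():.0f}]")
print(f"body volume: {b.body.volume_cc:.0f} cc, GTV volume: {b.gtv.volume_cc:.0f} cc")
print(f"max ground-truth displacement: {b.true_dvf.magnitude.max():.2f} mm")

rep = similarity_report(b.dct, b.pct, b.body)
print(f"dCT vs pCT over the body: MAE {rep.mae_HU:.1f} HU, SSIM {rep.ssim:.3f}, "
      f"NCC {rep.ncc:.3f}, GMSD {rep.gmsd:.3f}")
# The MAE quantifies how much the couch difference and inter-scan deformation
# separate the two acquisitions before any processing.
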