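"""Paint a lattice dose, evaluate DVH metrics, and re-fit spheres from the
50% isodose.

The painter is a stand-in for a treatment planning system: ablative peaks at
the sphere centers (median sphere dose = prescription) over a 30%-of-
prescription valley inside the GTV. The isodose fitter then recovers sphere
contours from the dose alone, the route used to compare plans on different
image sets.
"""

import numpy as np

from latticeplan import dvh_metrics, fit_spheres_from_isodose, synth_lattice_dose
from latticeplan.grids import ImageVolume
from latticeplan.lattice import SphereSet, rasterize_spheres
from latticeplan.phantom import ellipsoid_mask

shape, spacing = (80, 72, 64), (2.0, 2.0, 2.0)
origin = -(np.array(shape) - 1) / 2.0 * np.array(spacing)
ref = ImageVolume(np.zeros(shape), spacing, origin)
gtv = ellipsoid_mask(ref, (0, 0, 0), (60, 50, 50))

centers = np.array([[-30.0, 0.0, -20.0], [30.0, 0.0, -20.0], [0.0, 10.0, 25.0]])
spheres = SphereSet(centers, 15.0)
dose = synth_lattice_dose(spheres, gtv, prescription_cGy=2000.0, valley_ratio=0.3)

m_gtv = dvh_metrics(dose, gtv, 2000.0)
print("GTV DVH:", {k: round(v, 1) for k, v in m_gtv.as_dict().items()})

_, union = rasterize_spheres(spheres, gtv)
m_sph = dvh_metrics(dose, union, 2000.0)
print(f"all-spheres D50%: {m_sph.D50:.0f} cGy (prescription 2000, tolerance +-50)")

fitted = fit_spheres_from_isodose(dose, 2000.0, level_fraction=0.5)
print(f"isodose fit recovered {len(fitted)} spheres; centroid error "
      f"{np.abs(np.sort(fitted.centers_mm, 0) - np.sort(centers, 0)).max():.2f} mm")
# For a large GTV holding few spheres the GTV-wide percentiles sit on the
# valley plateau (here 600 cGy = 30% of prescription) while the sphere
# contours receive the full prescription at their median — the deliberate
# peak-valley heterogeneity of a lattice plan.
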