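"""Train the toy deformation-field model and predict a synthetic CT.

The network maps a couch-removed diagnostic CT to a dense displacement field;
warping the dCT by that field yields the synthetic CT, so no intensities are
invented — every sCT voxel is an interpolated dCT voxel.
"""

import numpy as np

from latticeplan import ModelSpec, PhantomSpec, make_phantom, predict_sct, train
from latticeplan.preprocess import remove_couch
from latticeplan.metrics import mae, ssim

pairs = []
for i in range(4):
    spec = PhantomSpec(grid_shape=(64, 64, 32), spacing=(3.0, 3.0, 4.0),
                       body_semiaxes_mm=(80.0, 55.0), lung_semiaxes_mm=(30.0, 35.0, 50.0),
                       body_z_halfextent_mm=56.0, gtv_center_mm=(30.0, 5.0, 0.0),
                       gtv_semiaxes_mm=(22.0, 20.0, 20.0),
                       sag_amplitude_mm=4.0, deform_amplitude_mm=1.0, noise_sd=2.0,
                       seed=100 + i)
    b = make_phantom(spec)
    d, _ = remove_couch(b.dct)
    p, _ = remove_couch(b.pct)
    pairs.append((d, p))

model = train(pairs, ModelSpec(levels=2, start_channels=8, epochs=30, lr=3e-3, seed=0))
print(f"training loss: {model.loss_trace[0]:.3g} -> {model.loss_trace[-1]:.3g} "
      f"({model.n_parameters} parameters)")

m_d = np.mean([mae(d, p) for d, p in pairs])
m_s = np.mean([mae(predict_sct(model, d)[0], p) for d, p in pairs])
s_d = np.mean([ssim(d, p) for d, p in pairs])
s_s = np.mean([ssim(predict_sct(model, d)[0], p) for d, p in pairs])
print(f"MAE  dCT vs pCT: {m_d:.2f} HU   sCT vs pCT: {m_s:.2f} HU")
print(f"SSIM dCT vs pCT: {s_d:.4f}     sCT vs pCT: {s_s:.4f}")
# The sCT should sit closer to the pCT than the raw dCT on both metrics: the
# model has absorbed the systematic couch-induced deformation.
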