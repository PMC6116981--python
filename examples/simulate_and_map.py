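"""Simulate a brain phantom and run the full water-content mapping chain.

Builds a 48^3 WM/GM/CSF phantom with smooth transmit/receive fields and B0
inhomogeneity, simulates the two multi-echo GRE acquisitions (7 and 40 deg,
TR 50 ms, 18 echoes), runs B1+-corrected T1 fitting, T2* fitting with the
field-gradient echo cutoff, M0 correction and CSF calibration, and compares
the recovered maps to the ground truth.
"""

import numpy as np

import mriwater as mw

bp = mw.make_brain_phantom(grid=(48, 48, 48))
spec = bp.spec
low = mw.simulate_megre(spec, mw.MEGRE_LOW, seed=1)
high = mw.simulate_megre(spec, mw.MEGRE_HIGH, seed=2)

maps = mw.fit_pipeline(
    low, high,
    b1plus_source=spec.b1plus_true,          # transmit field (here: known exactly)
    csf_prob=bp.probabilities["csf"],         # segmentation for the CSF reference
    b1minus=spec.b1minus_true,                # receive field (here: known exactly)
    rule=mw.NormalisationRule(ellipsoid=bp.ventricle_ellipsoid),
)

print(f"calibration factor C_norm = {maps.h2o.c_norm:.4f} "
      f"({maps.report['norm_mask_voxels']} ventricular CSF voxels)")
print(f"{'tissue':6s} {'H2O est':>8s} {'H2O true':>8s} {'T1 est':>8s} {'T1 true':>8s} "
      f"{'T2* est':>8s} {'T2* true':>8s}")
for name in ("wm", "gm", "csf"):
    m = bp.mask(name)
    print(f"{name:6s} {np.nanmean(maps.h2o.h2o[m]):8.2f} {spec.h2o_true[m].mean():8.2f} "
          f"{np.nanmean(maps.t1.t1[m]):8.1f} {spec.t1_true[m].mean():8.1f} "
          f"{np.nanmean(maps.t2star.t2star[m]):8.2f} {spec.t2star_true[m].mean():8.2f}")
print("\nH2O is percent of pure water (CSF = 100 by calibration); T1/T2* in ms.")
print("On noiseless data the chain inverts the signal model almost exactly.")
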