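"""Transmit-field mapping from a simulated AFI acquisition.

Shows the closed-form flip-angle estimate (small-TR approximation of the
two-TR steady state) and the exact-model refinement, which removes the
few-percent approximation bias.
"""

import numpy as np

import mriwater as mw

bp = mw.make_brain_phantom(grid=(32, 32, 32))
# AFI is acquired at lower resolution than the meGRE, as on the scanner
pair = mw.simulate_afi(bp.spec, mw.AFI_DEFAULT, grid=(16, 16, 16),
                       voxel_size=bp.spec.voxel_size * 2)

alpha0 = mw.afi_flip_angle(pair)                       # arccos((r n - 1)/(n - r))
alpha = mw.afi_refine(alpha0, pair, t1_assumed=1000.0)  # exact steady-state inversion
b1 = mw.b1plus_calibrate(alpha, pair.protocol.flip_nominal)
b1_grid = mw.resample_to_grid(b1.b1plus, pair.affine, bp.spec.shape, bp.spec.affine)

m = bp.brain_mask & np.isfinite(b1_grid)
err0 = mw.b1plus_calibrate(alpha0, 40.0).b1plus
err0 = np.nanmax(np.abs(mw.resample_to_grid(err0, pair.affine, bp.spec.shape,
                                            bp.spec.affine)[m] - bp.spec.b1plus_true[m]))
err1 = np.nanmax(np.abs(b1_grid[m] - bp.spec.b1plus_true[m]))
print(f"B1+ range in brain: {b1_grid[m].min():.3f} - {b1_grid[m].max():.3f} "
      "(relative to the nominal flip angle)")
print(f"max |error| closed form : {err0:.4f}")
print(f"max |error| refined     : {err1:.4f}")
print("\nThe closed form alone is biased by a few percent at TR1 = 125 ms;")
print("inverting the exact two-TR steady state removes that bias (residual")
print("error here comes from resampling and the nominal-T1 assumption).")
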