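"""T1 and T2* fitting on single voxels, including the echo-time cutoff.

Demonstrates (1) the two-point T1 fit recovering T1 exactly from noiseless
signals, (2) the weighted log-linear T2* fit, and (3) how a strong local
field gradient corrupts late echoes and why the voxel-wise TE_max bound
reduces the resulting T2* bias.
"""

import numpy as np

import mriwater as mw
from mriwater.relaxometry import FieldGradientMap

# --- T1: two flip angles, shared echo times -------------------------------
ones = np.ones((1, 1, 1))
spec = mw.PhantomSpec(voxel_size=(1, 1, 1), h2o_true=ones * 70, t1_true=ones * 1350,
                      t2star_true=ones * 60, b1plus_true=ones * 1.1, b1minus_true=ones)
low = mw.simulate_megre(spec, mw.MEGRE_LOW)
high = mw.simulate_megre(spec, mw.MEGRE_HIGH)
t1map = mw.fit_t1_two_point(low, high, spec.b1plus_true)
print(f"true T1 = 1350 ms (B1+ = 1.10)  ->  fitted T1 = {t1map.t1.flat[0]:.2f} ms")

# --- T2*: weighted log-linear fit -----------------------------------------
te = mw.MEGRE_LOW.te_list
decay = mw.EchoTrainVolume(magnitude=(80 * np.exp(-te / 45.0))[None, None, None, :],
                           protocol=mw.MEGRE_LOW)
fit = mw.fit_t2star(decay)
print(f"true T2* = 45 ms              ->  fitted T2* = {fit.t2star.flat[0]:.4f} ms, "
      f"S0 = {fit.s0.flat[0]:.2f}")

# --- intravoxel dephasing and TE_max --------------------------------------
shape = (8, 4, 4)
g = 25.0  # Hz/mm off-resonance gradient along x -> 25 Hz spread per 1 mm voxel
x = np.arange(shape[0])[:, None, None] * 1.0
spec = mw.PhantomSpec(voxel_size=(1, 1, 1), h2o_true=np.full(shape, 70.0),
                      t1_true=np.full(shape, 1000.0), t2star_true=np.full(shape, 50.0),
                      b1plus_true=np.ones(shape), b1minus_true=np.ones(shape),
                      delta_f_true=np.broadcast_to(g * x, shape).copy())
vol = mw.simulate_megre(spec, mw.MEGRE_LOW)
field = mw.fieldmap_from_phase(vol)
inner = (slice(1, -1),)
without = mw.fit_t2star(vol).t2star[inner]
print(f"\n25 Hz/mm gradient, true T2* = 50 ms:")
print(f"  no echo cutoff               : bias {without.mean() - 50:+7.2f} ms")
for q in (0.5, 0.25):
    fieldmap = mw.compute_te_max(field, spec.voxel_size, q_threshold=q)
    with_cut = mw.fit_t2star(vol, te_max=fieldmap).t2star[inner]
    print(f"  cutoff q = {q:4.2f} (TE_max = {fieldmap.te_max[2, 0, 0]:4.1f} ms): "
          f"bias {with_cut.mean() - 50:+7.2f} ms")
print("Dropping echoes beyond TE_max shrinks the dephasing-induced bias; the")
print("default q = 0.5 cuts at the sinc null, a stricter q excludes echoes")
print("that are already attenuated and helps more at extreme gradients.")
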