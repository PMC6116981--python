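"""Monte Carlo selection of the two flip angles at TR = 50 ms, SNR = 20.

For each candidate pair the script simulates noisy acquisitions of a
WM-like voxel, recovers water content and T1, and keeps the pairs whose
relative bias and standard deviation all stay below 10 %.
"""

import mriwater as mw

grid = mw.OptimGrid(
    alpha1_values=(3.0, 5.0, 7.0, 9.0, 11.0),
    alpha2_values=(20.0, 30.0, 40.0, 50.0, 60.0),
    tr=50.0, snr=20.0, n_reps=1000, seed=1,
)
result = mw.monte_carlo_optimize(grid, tolerance_pct=10.0)
table = mw.summarize_feasible(result)

print(f"{int(result.feasible_mask.sum())} of "
      f"{result.feasible_mask.size} flip-angle pairs are feasible at SNR 20:\n")
print(table.to_string(index=False, float_format=lambda v: f"{v:.2f}"))

i = grid.alpha1_values.index(7.0)
j = grid.alpha2_values.index(40.0)
print(f"\nOperating point (7, 40): bias/sd H2O = {result.bias_h2o[i, j]:.2f}/"
      f"{result.sd_h2o[i, j]:.2f} %, bias/sd T1 = {result.bias_t1[i, j]:.2f}/"
      f"{result.sd_t1[i, j]:.2f} %")
print("The table ranks pairs by combined standard deviation; lower is more precise.")
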