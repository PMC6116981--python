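# mriwater

Quantitative mapping of free water content (H₂O), longitudinal relaxation
time (T₁) and effective transverse relaxation time (T₂\*) of the human brain
from two spoiled multi-echo gradient-echo (meGRE) acquisitions plus an
actual-flip-angle-imaging (AFI) transmit-field acquisition — together with a
forward signal simulator and digital phantoms that make every processing
stage verifiable by parameter recovery.

The package is aimed at quantitative-MRI researchers who want a transparent,
fully testable implementation of two-point relaxometry and water-content
calibration: each stage is an importable function operating on NumPy volumes,
with NIfTI I/O and a thin command-line wrapper on top.

## The method

The spoiled gradient-echo signal at echo time TE is

```
S(TE) = M₀ · exp(−TE/T₂*) · sin(α_eff) · (1 − E)/(1 − E·cos α_eff) · B₁⁻ ,
        E = exp(−TR/T₁),  α_eff = B₁⁺ · α_nom
```

Two meGRE acquisitions share TR = 50 ms and 18 echoes (TE₁ = 2.2 ms,
ΔTE = 2.55 ms) but differ in nominal flip angle (7° → M₀-weighted, 40° →
T₁-weighted). The processing chain:

1. **B₁⁺** from a two-TR AFI acquisition (TR₁ = 125 ms, TR₂/TR₁ = 5, 40°):
   closed-form estimate `α ≈ arccos((r·n − 1)/(n − r))` with r = S₂/S₁,
   refined by inverting the exact two-TR steady state, then calibrated by
   the nominal flip angle and resampled to the meGRE grid.
2. **T₁** per voxel from `argmin_T₁ Σₙ |S₇°(TEₙ)/C(T₁,α₇°) − S₄₀°(TEₙ)/C(T₁,α₄₀°)|²`
   over the first three echoes (the shared T₂\* weighting cancels);
   estimates above 6 s are clipped.
3. **T₂\*** by a weighted log-linear fit (weights |S(TEₙ)|) restricted per
   voxel to echoes below TE_max, a bound derived from the local gradient of
   the off-resonance field; estimates above 1.5 s are clipped.
4. **M₀** from the low-flip acquisition: the first three echoes divided by
   the three correction factors (T₂\* decay, T₁/B₁⁺/α saturation, receive
   field B₁⁻ — supplied or estimated by a clustering + polynomial bias-field
   scheme) and averaged.
5. **H₂O** by calibration to ventricular CSF (≈100 % water): voxels with CSF
   probability ≥ 0.99, T₁ > 2900 ms and T₂\* > 500 ms inside an ellipsoid
   around the lateral ventricles define the scalar C_norm with
   H₂O = C_norm · M₀.

A forward simulator (SPGR + exact AFI steady state, intravoxel-dephasing
attenuation, Rician noise), an 8-tube H₂O/D₂O dilution phantom, a WM/GM/CSF
brain phantom, a long-TR gold-standard water-content variant, first-order
T₁-bias error propagation, and Monte Carlo flip-angle optimisation complete
the package.

## Worked example

`python examples/simulate_and_map.py` simulates a 48³ brain phantom, runs the
full chain with known transmit/receive fields and prints:

```
calibration factor C_norm = 1.0000 (448 ventricular CSF voxels)
tissue  H2O est H2O true   T1 est  T1 true  T2* est T2* true
wm        69.91    69.90    988.0    988.0    51.93    52.00
gm        80.82    80.80   1580.0   1580.0    56.83    57.00
csf      100.00   100.00   4000.0   4000.0   798.98   800.00
```

H₂O is percent of pure water (CSF = 100 by calibration), T₁/T₂\* in ms: on
noiseless data the chain inverts the forward model almost exactly, tissue by
tissue. The other examples cover B₁⁺ mapping (`b1_mapping.py`), voxel-level
relaxometry and the TE_max cutoff (`relaxometry_voxel.py`), tube-phantom
validation at SNR 100 (`tube_phantom_validation.py`), flip-angle optimisation
(`optimize_flip_angles.py`) and T₁-bias propagation (`error_propagation.py`).

## Command line

```bash
mriwater simulate --kind brain --grid 64 --out sim/      # phantom + acquisitions
mriwater fit-b1  --s1 sim/afi_s1.nii.gz --s2 sim/afi_s2.nii.gz --out b1.nii.gz
mriwater run     --config pipeline.yaml                  # full chain from YAML
mriwater optimize --snr 20 --out feasible.csv
```

`mriwater run` (alias `fit-h2o`) writes all parameter maps, the normalisation
mask and a JSON report with C_norm and per-stage quality counters.

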