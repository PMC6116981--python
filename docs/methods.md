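# Methods

This note documents the models, numerical choices and limitations of the
package, in the spirit of a methods appendix.

## Signal model and assumptions

All fitting assumes the perfectly spoiled gradient-echo steady state

S(TE) = M₀ · C_T₂\*(TE) · C_T₁,B₁⁺,α · C_B₁⁻, with
C_T₂\*(TE) = exp(−TE/T₂\*),
C_T₁,B₁⁺,α = sin(α_eff)·(1 − E)/(1 − E·cos α_eff), E = exp(−TR/T₁),
α_eff = B₁⁺·α_nom, and C_B₁⁻ = B₁⁻.

Assumptions inherited from this model: perfect spoiling of transverse
magnetisation (the relatively long TR = 50 ms keeps unspoiled contributions
small, but they are not modelled), identical T₁ weighting in both
acquisitions, no magnetisation-transfer or direct-saturation effects, and a
mono-exponential T₂\* decay valid only below the voxel-wise echo-time bound
described below.

The AFI forward model is the exact periodic steady state of the alternating
two-TR pulse train,

Mz₁ = M₀(1 − E₂ + c·E₂(1 − E₁))/(1 − c²E₁E₂), Eᵢ = exp(−TRᵢ/T₁), c = cos α,

(Mz₂ symmetric), not the small-TR approximation; echo-time decay is not
modelled because it cancels in the S₂/S₁ ratio.

## B₁⁺ estimation

The closed form α ≈ arccos((r·n − 1)/(n − r)) is exact only in the limit
TRᵢ ≪ T₁; at TR₁ = 125 ms it under-reads a 40° flip by ≈ 1.2 % (T₁ = 1 s) and
up to ≈ 5 % over α ∈ [20°, 60°], T₁ ∈ [0.5, 4.5] s. The refinement inverts
the exact ratio, which for fixed T₁ is rational-linear in cos α:

cos α = [(1 − E₁) − r(1 − E₂)] / [r·E₂(1 − E₁) − E₁(1 − E₂)].

Because this inversion is algebraic, the "iterative" refinement reduces to a
single exact solve; voxels whose inverted cosine falls outside [−1, 1] by
more than 10⁻³ keep the closed-form value and are flagged. The assumed T₁
(default 1000 ms, white matter) is the only approximation left: a ±50 %
mismatch leaves a residual flip-angle error below ≈ 2.5 %, of the same order
as the closed-form bias it replaces. arccos arguments exceeding the valid
range by ≤ 10⁻³ (noise) are clamped silently; larger excesses invalidate the
voxel. B₁⁺ maps are median-filtered (radius 1 voxel, configurable, 0
disables) before trilinear resampling to the meGRE grid — transmit fields
are smooth at the AFI resolution, so the filter suppresses ratio speckle
without biasing the field.

## T₁ fitting

T₁ minimises the summed squared difference of the two saturation-corrected
signals over the first three echoes. Because the correction factor is
echo-independent, the per-voxel objective reduces to a quadratic form in the
three echo cross-sums, making each candidate evaluation O(voxels). The
solver is a 128-point log-spaced coarse scan over [1, 6000] ms (the
objective can be multimodal on noisy voxels) followed by vectorised
golden-section refinement to 0.01 ms; an exhaustive 0.1 ms grid search is
kept in the test suite as the oracle. Estimates at the upper bound are
clipped to 6 s and flagged — the longest brain T₁ (CSF) lies below that.
Three echoes balance SNR against signal loss from dephasing at late echoes;
the count is configurable and matches the M₀ average.

## T₂\* fitting and the echo-time bound

T₂\* comes from closed-form weighted least squares of ln S on TE with weights
|S(TEₙ)|, which approximates the maximum-likelihood estimator at high SNR
(the variance of ln S is inversely proportional to S²; the |S| weighting is
a robust compromise that the test suite shows beats unweighted log fitting).
Non-decaying voxels and estimates above 1.5 s are clipped with a flag.

Macroscopic field gradients superimpose a through-voxel dephasing on the
mono-exponential decay. The simulator models a linear gradient across each
voxel axis as a separable attenuation |sinc(Gᵢdᵢ·TE)| (normalised sinc,
Gᵢ in Hz/mm, dᵢ the voxel size in mm), whose first null occurs when the
through-voxel dispersion reaches one cycle. The fit is restricted to echoes
below TE_max = q/(rate/2) with rate = ‖(Gᵢdᵢ)‖₂ and q the dispersion across
*half* the voxel in cycles; the default q = 0.5 places the bound exactly at
the sinc null. This is a permissive default — echoes just below the null are
already strongly attenuated — but the |S| weighting suppresses them, and a
stricter q (e.g. 0.25) measurably reduces the residual bias at extreme
gradients (see `examples/relaxometry_voxel.py`). Every voxel keeps at least
the first three echoes regardless of TE_max (flagged), so the fit never
degenerates where the field is worst.

The off-resonance field itself is estimated from the echo phases assuming
zero phase at TE = 0: the two-echo estimate Δφ/(2πΔTE) is disambiguated
against integer aliases of 1/ΔTE by scoring the wrapped residuals of all
echoes (possible because TE₁ is not a multiple of ΔTE), then refitted by
least squares through the origin. Scanner phase offsets violate the
zero-offset assumption; real data with unknown coil phase should supply an
external field map instead. Spatial unwrapping is not performed — temporal
unwrapping suffices for |Δf| well beyond the 196 Hz two-echo limit at
ΔTE = 2.55 ms. The gradient is estimated by central differences (one-sided
at borders) with the Euclidean norm across axes.

## M₀ correction and water-content calibration

M₀ averages the first three echoes of the low-flip acquisition divided by
the three correction factors; all corrections are evaluated with the
low-flip protocol because water content is derived from that acquisition
only. Voxels with any non-positive or undefined correction factor are marked
invalid rather than divided through.

The receive field is either supplied externally or estimated from the
T₂\*/T₁-corrected M₀ map by alternating (a) 3-class 1-D clustering of the
log-intensities with (b) a least-squares fit of a 3-D polynomial of total
degree ≤ 4 to the log-residuals inside the brain mask, normalised to mean 1.
Class seeding is farthest-point from the median rather than quantiles:
ventricular CSF is only a percent of brain voxels and quantile seeding never
places a centre on it, collapsing two centres onto white matter. On the
brain phantom the scheme recovers a ±15 % polynomial field to ≈ 0.01 % RMS;
the 2 % RMS contract leaves headroom for less idealised inputs. The
constant-offset ambiguity between class centres and the polynomial is fixed
by zero-meaning the log-field each iteration.

Calibration: the normalisation mask is the conjunction CSF probability
≥ 0.99, T₁ > 2900 ms, T₂\* > 500 ms, intersected with an ellipsoid around
the lateral ventricles (world coordinates; the brain phantom exports a
bounding ellipsoid of its ventricle pair as the default). C_norm =
100 / mean(M₀ | mask), so the mask mean of H₂O is exactly 100 % by
construction and any global signal scale cancels.

The long-TR variant (TR = 10 s, 90°, 32 echoes) skips the T₁/B₁⁺ correction
entirely: S₀ from the T₂\* fit, receive-field division, and the same
calibration. Even TR = 10 s leaves exp(−TR/T₁) ≈ 8 % saturation of
ventricular CSF (T₁ ≈ 4 s), which inflates the calibration factor and the
tissue values normalised with it — the simulator reproduces this known bias
of long-TR referencing, and the function warns when TR < 5× the stated
longest tissue T₁ (default 2000 ms, parenchyma).

First-order error propagation: an H₂O error from a T₁ bias δT₁ is
|∂ln C_T₁,B₁⁺,α/∂T₁|·δT₁ with the analytic derivative
(TR·E/T₁²)·[cos α/(1 − E cos α) − 1/(1 − E)]. At the 7° acquisition the
sensitivity grows with T₁, so identical relative T₁ errors hurt CSF several
times more than white matter; since CSF feeds the calibration mask, a CSF
T₁ bias rescales all tissue values through C_norm.

## Digital phantoms

The tube phantom emulates an H₂O/D₂O dilution series: eight disjoint
cylinders on a zero-signal background spanning 50–100 % water with
MnSO₄-shortened T₁ (400–2200 ms, fixture values chosen as a realistic
spread; one tube at exactly 100 % for calibration), uniform T₂\* = 60 ms,
uniform fields.

The brain phantom is piecewise constant over WM / GM / CSF with values from
the method's reported tissue means (WM 69.9 % / 988 ms / 52 ms, GM 80.8 % /
1580 ms / 57 ms) and ventricular CSF set to 100 % / 4000 ms / 800 ms
(typical 3 T values; CSF T₂\* chosen above the 500 ms normalisation floor as
in well-shimmed ventricles). Geometry: GM shell over WM core in a brain
ellipsoid, two central ventricle ellipsoids labelled CSF with crisp (0/1)
class probabilities. Fields are smooth low-order polynomials: centre-bright
quadratic B₁⁺ (±7.5 %), degree-3 B₁⁻ (≈ ±15 %), and a quadratic-plus-cross-
term off-resonance surface of 25 Hz amplitude whose gradients stay below
≈ 1 Hz/mm — representative of a well-shimmed brain away from air–tissue
interfaces. What the phantom does **not** emulate: partial-volume mixing at
tissue borders, susceptibility hot spots near sinuses (tens of Hz/mm),
anatomical texture within classes, imperfect spoiling, motion, and scanner
phase offsets. Passing recovery tests therefore demonstrate correctness of
the inversion chain under the stated model, not robustness to these effects.

Noise is additive complex Gaussian before the magnitude (Rician magnitude;
Rayleigh floor σ√(π/2) on zero signal), with SNR defined as true first-echo
signal over σ in a stated reference region. All stochastic operations take
explicit seeds.

## Flip-angle optimisation

For each (α₁, α₂) pair, 1000 noisy single-voxel acquisitions of a WM-like
reference (70 % / 1000 ms / 50 ms) are simulated at the pair's own
first-echo SNR (σ = S_low(TE₁)/SNR), pushed through the T₁ fit and the M₀
chain with known fields, and summarised as relative bias and standard
deviation of H₂O and T₁ in percent of truth; a pair is feasible when all
four stay below 10 %. Each pair derives its random stream from the global
seed and its own flip angles, so results are independent of grid ordering.
Degenerate pairs (α₁ = α₂) make T₁ unidentifiable and receive infinite
metrics. An optional convergence mode doubles the repetition count until no
metric moves by more than a set tolerance; the default is a fixed count for
strict determinism. At TR = 50 ms and SNR = 20 the (7°, 40°) operating point
sits inside the feasible region (bias ≲ 0.4 %, sd ≲ 6 %), and the region is
empty at SNR = 2.

## Evaluation helpers

Tissue statistics mirror the histogram analysis used for in vivo
comparisons: probability-thresholded masks (default 0.99), Freedman–Diaconis
binning, an unweighted least-squares Gaussian fit returning (μ, σ), and a
fallback to the histogram mode (recorded in the result) when the fit fails
or degenerates — the behaviour broad, overlapping T₂\* distributions
provoke. Recovery metrics are plain bias / RMSE / CV against simulator
truth.

## Problem sizes and tolerances

Default verification sizes: 64³ brain phantom for end-to-end and bias-field
recovery, 1000 voxels for solver-oracle comparisons, 9×9 (α, T₁) grids for
AFI round trips, 1000 Monte Carlo repetitions per flip-angle pair. Solver
tolerances: 0.01 ms (T₁ golden section), 10⁻³ (arccos clamping), 10⁻⁴
(bias-field log-convergence), 20 alternations maximum with a warning on
non-convergence. All are configurable through `FitConfig`.

## Known limitations

- Perfect spoiling is assumed end to end; imperfect-spoiling corrections are
  out of scope.
- The field-map estimator assumes zero phase at TE = 0 (no coil phase
  offset) and performs no spatial unwrapping.
- The receive-bias estimator expects a handful of intensity classes inside
  the mask; it is validated on piecewise-constant phantoms, not on real
  anatomy with continuous partial-volume mixtures.
- Segmentation, registration to standard space and ROI atlases are outside
  the package; CSF probabilities and (for real data) brain masks must be
  supplied.
- The mono-exponential T₂\* model with a hard echo cutoff leaves residual
  bias in voxels whose early echoes are already dephased; multi-compartment
  or complex-valued models are not provided.
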