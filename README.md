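# ctvent — robust CT-ventilation imaging

`ctvent` reconstructs regional lung-ventilation surrogates from an
inhale/exhale CT image pair and a deformable-image-registration (DIR)
displacement field. It implements the *robust* family of CT-ventilation
methods, in which the Jacobian factor det J of the respiratory deformation is
not differentiated voxel by voxel but recovered from many **subregional
volume-change measurements whose statistical uncertainty is explicitly
controlled** by a tolerance parameter τ. It is aimed at medical-physics and
image-analysis researchers who want a fully testable, phantom-verifiable
implementation of these methods without access to clinical 4DCT/SPECT data.

## The method

For a subregion Ω of the exhale (reference) lung Ω(R), the deformed volume is
vol_ϕ(Ω) = ∫_Ω det J(x) dx. Two estimators of this integral are provided:

* **IJF** (Integrated Jacobian Formulation, transformation based) — a
  hit-or-miss Monte-Carlo estimate: every inhale lung voxel x with
  ϕ⁻¹(x) ∈ Ω is a *hit*, and b = H, the hit count, estimates the deformed
  volume in unit-voxel units. The binomial standard error of the hit
  proportion yields a minimum hit count H\*(τ) for a 95% relative-error
  guarantee (β = 1.96): β·√(H(1−H/M))/H ≤ τ, with M = |Ω(T)|.
* **MCVC** (Mass Conserving Volume Change, intensity based) — assuming the
  HU changes are caused solely by air-content changes,
  b = R̄_Ω / T̄_ϕ(Ω) · |Ω|, the ratio of mean reference to mean deformed-target
  density (linear HU→density calibration: air −1000 HU → 0, water 0 HU → 1
  g/cm³). Its uncertainty criteria require |Ω| ≥ β²/τ² and H ≥ β²/τ².

Subregions are seeded by dart throwing (Poisson-disk sampling) and grown by
morphological dilation with a box structuring element until the τ-criterion
passes — smaller τ, larger regions, lower resolution, higher robustness.

The ventilation image V(x) is parameterized with Shepard moving least
squares over L dart-thrown knots z_j: v_i = Σ_j C_ij q_j, with row-stochastic
Gaussian weights C_ij = w(‖x_i−z_j‖)/Σ_l w(‖x_i−z_l‖), w(r) = exp(−σr²).
The K × L data matrix Â = AC is accumulated from region voxel lists without
forming the dense 0/1 membership matrix A, and the knot values solve

    min_q ‖Âq − b‖² + λ Σ_k (q_k − h/N)²   s.t.  Σ_i v_i = h,  q_k ≥ ε,

a strictly convex quadratic program (primal active-set solver) whose
equality constraint pins the global volume change h (h_IJF = |Ω(T)|;
h_MCVC = R̄_Ω(R)/T̄_Ω(T)·|Ω(R)|) and whose bounds guarantee strictly positive
Jacobian estimates, since V = Cq is a convex combination. The ventilation
signal is the absolute volume difference V − 1 (exhale reference).

The package also ships a **synthetic phantom generator** (lung-shaped masks,
diffeomorphic deformations with closed-form det J, mass-consistent HU pairs,
a degraded low-resolution reference standing in for SPECT ventilation) and
the **evaluation harness**: affine resampling, slicewise 3×3 median
filtering, masked voxelwise Spearman correlation, the 30-value τ sweep over
[0.01, 0.25], five-number summaries, and an exact paired Wilcoxon
signed-rank test.

## Worked example

Generate a phantom with a known sinusoidal Jacobian field, reconstruct the
IJF ventilation image at τ = 0.07, and compare it with the ground truth:

```python
import numpy as np
from scipy.stats import spearmanr
from ctvent import PhantomSpec, generate_phantom
from ctvent.pipeline import PreparedCase

spec = PhantomSpec(grid_dims=(96, 96, 72), spacing_mm=(2, 2, 2),
                   deformation="sinusoid", amplitude_mm=(2, 2, 2),
                   wavelength_mm=(40, 40, 40), seed=11)
case = generate_phantom(spec)
prep = PreparedCase(case.reference_image, case.target_image, case.mask_R,
                    case.mask_T, case.inverse_displacement,
                    knot_spacing_mm=12.0, subdomain_spacing_mm=5.0, seed=5)
result = prep.ventilate("IJF", tau=0.07)
rho = spearmanr(result.v_values,
                case.true_jacobian.data[case.mask_R.data]).statistic
K = sum(1 for e in prep.estimates("IJF", 0.07) if e.tolerance_met)
print(f"L = {prep.model.n_knots} knots, K = {K} subregional measurements, "
      f"N = {prep.N} lung voxels")
print(f"Spearman(recovered, true det J) = {rho:.3f}")
```

prints (exactly, for these seeds):

```
L = 240 knots, K = 1828 subregional measurements, N = 54254 lung voxels
Spearman(recovered, true det J) = 0.955
```

i.e. the recovered ventilation image ranks the ~54k lung voxels almost
identically to the true Jacobian field. The bundled 15-case table of
per-case method-vs-SPECT correlations can be summarized from the CLI:

```bash
ctvent evaluate table --csv src/ctvent/data/example_method_correlations.csv
```

which reports median/min/max of 0.82 / 0.12 / 0.90 for IJF and
0.48 / −0.06 / 0.84 for MCVC, and a paired signed-rank comparison
(W⁻ = 11, exact two-sided p ≈ 0.0034) showing the transformation-based
method correlating better than the intensity-based one.

Other CLI verbs: `ctvent phantom generate`, `ctvent ventilate run|sweep`,
`ctvent evaluate correlate`.

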