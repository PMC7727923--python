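# Methods

This note documents the models, numerical choices and limitations of
`ctvent`. Symbols: ϕ is the DIR transformation mapping the exhale
(reference) lung Ω(R) onto the inhale (target) lung Ω(T); J its Jacobian;
N = |Ω(R)|, M = |Ω(T)| in voxels; τ the uncertainty tolerance; β = 1.96 the
two-sided 95% Gaussian quantile.

## Subregional estimators and uncertainty model

Both estimators measure vol_ϕ(Ω) = ∫_Ω det J dx for many subregions
Ω_k ⊂ Ω(R) and treat the measurement uncertainty as Gaussian.

**IJF.** The membership oracle f(x) = 1 iff ϕ⁻¹(x) ∈ Ω is evaluated at every
target lung voxel center; membership is decided by *nearest-center binning*
(the oracle is binary, not an interpolating splat), and positions binned
outside the reference image count as misses (logged). The estimate is b = H
(unit-voxel volumes). Modeling the hit proportion as binomial, the relative
standard error of the estimated volume is √(H(1−H/M))/H, and the tolerance
criterion is β·√(H(1−H/M))/H ≤ τ, which defines the minimum hit count H\*(τ)
implicitly. The rule is config-exposed (`beta`, or an alternative callable)
because the literature defines H\* only qualitatively as a function of M.

**MCVC.** With the linear HU→density calibration ρ = (HU+1000)/1000 clamped
at 0 (air −1000 HU → 0 g/cm³, water 0 HU → 1 g/cm³), mass conservation gives
b = R̄_Ω / T̄_ϕ(Ω) · |Ω|. The target-side mean is computed over exactly the
hit set of the region, so its sample size is H. The default tolerance
criteria are |Ω| ≥ β²/τ² **and** H ≥ β²/τ² — the printed form of the
standard-error bounds, with densities implicitly normalized to unit scale.
A plug-in alternative (`mcvc_mode="adaptive"`) replaces β²/τ² by
(β·σ̂/(μ̂·τ))² with the in-region sample SD and mean (a coefficient-of-
variation form; the raw σ̂/τ form is dimensionally inconsistent because σ̂
carries g/cm³ while τ is relative). The adaptive form degenerates on locally
constant densities — a single voxel has σ̂ = 0 and passes — which is why the
fixed form is the default. Regions whose mean hit density falls below
10⁻³ g/cm³ are invalidated (ratio blow-up) rather than clamped.

## Sampling and region growth

Knots and subdomain seeds are placed by dart throwing: all mask voxel
centers are visited in a seeded random order and accepted iff at least the
nominal spacing from every accepted point. This is deterministic given the
seed, approximately maximal, and yields ≈ 0.38·V/((4π/3)(d/2)³) points in a
volume V at spacing d (≈ 150 knots for a 4.5 L lung at 30 mm).

Subregions grow from a single seed voxel by repeated dilation with a box
structuring element; after k dilations the candidate is the Chebyshev box of
radius k·(element radii) intersected with the lung mask, restricted to the
seed's 26-connected component (a box can straddle both lungs). Growth stops
at the first k whose region passes the tolerance predicate; seeds that never
pass within `max_dilations` (default 20) are dropped, not errors. Predicates
depend only on sums of voxelwise fields (hit counts, densities and their
squares) over the candidate region, so candidates are screened in O(1) with
3-D summed-area tables; the exact connected region is materialized and the
predicate re-verified on it before acceptance.

The structuring element is interpreted physically: the clinical 7×7×3
element on 1.27×1.27×3 mm voxels is ≈ 9 mm isotropic, so for isotropic
phantom voxels the default is 3×3×3 (the 7×7×3 dialect is available by
config).

## MLS parameterization

The field is a Shepard moving average, v = Cq, with Gaussian weights
truncated at 2.5× the nominal knot spacing and renormalized so every row of
C sums to one (partition of unity; the operator is bound-preserving with
∞-norm 1). σ defaults to ln 2 / d² (half weight at one knot spacing d),
tying the kernel width to knot density. A voxel with no knot inside the
truncation radius falls back to its nearest knot with weight 1 (counted and
logged). Â = AC is accumulated from the region voxel lists through a sparse
membership product; the dense K×N matrix A is never materialized, and peak
storage is O(nnz(C) + Σ_k|Ω_k| + K·L).

## Constrained solve

The recovery problem

min_q ‖Âq − b‖² + λ Σ(q_k − h/N)²  s.t. (1ᵀC) q = h, q ≥ ε

is strictly convex for λ > 0 and solved with a primal active-set method
(KKT solves on the free set; strictly feasible start q = h/N; multipliers
checked to 10⁻¹⁰ relative). Defaults: λ = 1 exactly as the objective is
written (the penalty is the variance of the knot values about the mean
volume change enforced by the equality constraint — large Jacobian spread
being a practical error indicator); ε = 0.05, a 95%-compression floor, far
from active on realistic fields. The equality constraint is expressed in
knot space, identical to Σv = h because C is row-stochastic. Feasibility
requires ε·N ≤ h; equality pins q ≡ ε (the unique feasible point) and is
returned directly. Every solve asserts q ≥ ε, V = Cq > 0 and
|Σv − h| ≤ 10⁻⁶·h. The signal is V − 1 for an exhale reference (expansion
positive), 1 − V for an inhale reference; both are monotone in V so
rank-based evaluation is unaffected.

## Evaluation harness

Comparison against a low-resolution reference ventilation: the signal (and
mask) are resampled onto the reference grid with a user-supplied affine
(identity for phantoms — estimating the transform is out of scope); the
reference is median-filtered per axial slice with a 3×3 window
(reduced-window at edges); the mask survives at ≥ 50% partial volume; the
Spearman correlation uses midranks and excludes missing voxels pairwise; a
constant field yields a *missing* correlation, never 0. The τ sweep uses 30
uniform values on [0.01, 0.25] by default; per-τ failures (e.g. K < L at
τ = 0.01) are recorded and the sweep continues. Summaries are five-number
(midpoint-interpolated percentiles). The paired Wilcoxon signed-rank test
drops zero differences, midranks ties, and computes the exact two-sided p
for n ≤ 25 by dynamic programming over the sign-flip distribution of doubled
midranks (equivalent to full 2ⁿ enumeration); a tie-corrected normal
approximation is used above. The reported p is twice the smaller tail,
capped at 1.

## Synthetic phantoms

Each case is a pair of HU volumes on a shared grid, lung masks in both
frames, the sampled inverse deformation (world-mm offsets on the target
grid), the closed-form det J on the reference grid, and a degraded
low-resolution reference. Anatomy: two half-ellipsoid "lungs" (flat medial
faces, slightly tilted off the lattice axes so voxel-center counting of the
flat face dithers rather than biasing volumes by half a voxel layer) inside
a water-density body cylinder; air outside. Deformation families: identity;
per-axis uniform scaling about the mask centroid; separable sinusoid
(diffeomorphic iff 2πA/λ < 1 per axis, rejected otherwise, as are
wavelengths under 4 voxels). The exhale frame is the reference, so
expansion phantoms have det J ≥ 1. Densities carry a smooth seeded
cosine-series texture (relative amplitude 0.1, correlation length ≈ 12 mm)
on a 0.25 g/cm³ exhale base; with `mass_conserving=True` the target density
is ρ_R(ϕ⁻¹(y))/det J(ϕ⁻¹(y)) exactly, before optional additive HU noise.

The target mask is the *discrete forward image* of the reference mask: a
target voxel is lung iff its inverse-mapped position bins (nearest center)
into a reference lung voxel. This matches the membership oracle's own
discretization and emulates mask-aligned DIR; it makes Σ det J over Ω(R)
agree with |Ω(T)| to a few 10⁻³ and removes an asymmetric surface hit loss
(~4% of whole-lung hits) that voxelizing the continuous deformed shape would
introduce.

The degraded reference blurs the true det J field (Gaussian, default FWHM
10 mm), resamples it to a coarser grid (default 6 mm), and adds Gaussian
noise with SD proportional to the local mean (default CV 0.1), truncated at
zero — rank-preserving in expectation, with no attempt to model emission or
reconstruction physics. A slab-shaped intensity-offset artifact can be
injected to mimic phase-binning errors; it has no literature-fixed
parameters and defaults to off.

**What the phantoms do not emulate:** real anatomy and vasculature, CT
reconstruction artifacts, intra-cycle blood-mass redistribution (the known
confounder of intensity-based estimation), DIR model error (the supplied
field *is* the truth), and emission physics. Passing phantom tests therefore
validates the numerics and the statistical machinery, not clinical accuracy.

## Problem sizes and experiment protocol

The default phantom grid is 64×64×48 at 3 mm isotropic (~0.43 L lungs;
a full reconstruction takes seconds). The sinusoid-recovery and
DIR-robustness experiments use 96×96×72 at 2 mm isotropic, whose 8 mm³
voxels are close to the clinical 1.27×1.27×3 mm: subregional resolution is
set by H\*(τ)·voxel-volume, and at τ = 0.03 the passing-region width must
stay below the 40 mm deformation wavelength for region averages to retain
the field's sign structure. For the same reason the phantom knot spacing is
12 mm (the clinical 30 mm default is appropriate for ~300 mm lungs, not
~100 mm phantoms; with 15 mm knots the MLS basis itself caps the achievable
Spearman against the sinusoidal truth at 0.95). Subdomain seeds are at 5 mm
(clinical default 7 mm), giving K ≈ 1800 measurements for L = 240 knots.
The DIR-perturbation experiment adds smooth vector noise of 0.5 voxel SD
per component with a 5-voxel correlation length (registration solutions for
lung CT are smooth at the centimeter scale).

## Known limitations

* **Lattice aliasing of hit counts.** For *uniform* scalings the preimages
  of target voxel centers form a regular lattice commensurate with the
  voxel grid; hit counts of box-grown regions then beat against it (moiré
  period ≈ 30 mm for a 1.1 scale on 3 mm voxels, comparable to the region
  width at τ = 0.05), inflating the per-region spread of H/|Ω| to ≈ ±9%
  where the binomial model predicts ±2.3%. Only ~56% of tolerance-passing
  regions meet their nominal 95% relative-error guarantee on such phantoms
  (verified against brute-force enumeration; independent of voxel size).
  Irregular (realistic) deformations decorrelate the preimage lattice and
  restore near-binomial behavior — the sinusoid phantom and MCVC (accurate
  to ~0.2% on the same phantom) are unaffected. The guarantee of the
  IJF tolerance rule should be read as conditional on non-degenerate
  deformations.
* The adaptive MCVC tolerance mode accepts arbitrarily small regions when
  the local density is constant (see above); it is provided for
  completeness, not as the default.
* Correlation masks at reference resolution use a 50% partial-volume
  threshold; whether clinical analyses mask at all is not standardized, and
  correlations on small masks are sensitive to this choice.
* The active-set solver is exact for the strictly convex default (λ > 0);
  λ = 0 with rank-deficient Â is rejected by the KKT solve rather than
  regularized silently.
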