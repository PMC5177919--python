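# Methods

This note records the models implemented in `icosaflow`, the defaults and why
they were chosen, what the synthetic phantom does and does not emulate, and
the numerical choices that affect results.

## Synthetic stenotic-jet phantom

The phantom stands in for a scale-resolving CFD solution of turbulent flow
through an axisymmetric pipe stenosis. It provides three things on a fine
cell-centred grid (default spacing 0.25 mm): a steady mean velocity field, a
prescribed symmetric positive-semidefinite Reynolds-stress tensor field, and
an ensemble of instantaneous velocity snapshots whose pointwise fluctuation
covariance equals that tensor.

**Geometry.** Upstream diameter D = 14.6 mm; the wall follows a raised-cosine
constriction of length D centred at x = 0,
r(x) = R₀ − (R₀ − r_t)(1 + cos 2πx/D)/2, with throat radius
r_t = R₀√(1 − s) for area reduction s ∈ {0.60, 0.75, 0.90} (any value in
(0,1) is accepted). An optional post-stenotic dilatation widens the wall to
`psd_factor`·R₀ over one further diameter through a second cosine blend. The
exact cosine profile is a documented stand-in: the phantom is a statistical
fixture, not a CFD replication, and any smooth cosine blend serves equally.

**Mean field.** A parabolic (Poiseuille-family) profile of radius r_p(x)
carries the volumetric flow rate Q = U_bulk πR₀² through every section, with
U_bulk = Re·μ/(ρD). Downstream of the throat minimum the profile radius
follows standard jet phenomenology: it separates at r_t, holds it over a
potential core (default 1.5 D), then spreads linearly (default rate 0.15)
until it re-attaches to the wall. The radial velocity
u_r = U_c r_p′(x) η(1 − η²), η = ρ_r/r_p, is the exact axisymmetric-continuity
partner of the parabolic profile, so streamlines follow the contracting and
spreading jet and the discrete axial flow rate is conserved to ≲0.1%
(tested at 1%). Fluid defaults are water-like: ρ = 997 kg/m³,
μ = 8.899×10⁻⁴ kg/(m·s).

**Turbulence.** The fluctuation model is a mixing-length closure: the axial
fluctuation std is σ_a = 2·I·U_c(x)·η, i.e. ℓ|∂u/∂r| with ℓ = I·r_p, with a
Gaussian tail (width 0.25 in η) into the recirculation region and an
asymmetric axial envelope that suppresses fluctuations in the accelerating
nozzle and peaks 1.5 D downstream of the throat (rise scale 0.8 D, decay
scale 2.5 D). Radial and azimuthal stds are 0.6 σ_a, and the axial–radial
correlation coefficient is +0.45, signed so that the shear stress
⟨u′_ax u′_r⟩ opposes the mean shear and turbulence production
P = −ρ⟨u′ᵢu′ⱼ⟩S_ij is positive throughout the prescribed field. The default
mixing-length ratio I = 0.15 puts edge fluctuations at 30% of the local
centreline velocity — representative of a transitional post-stenotic jet —
and was fixed once as a physical choice. The local tensor is rotated from the
(axial, radial, azimuthal) frame to Cartesian axes and stored packed
(xx, yy, zz, xy, xz, yz).

**Snapshots.** Each snapshot is mean + L·ξ with L the analytic Cholesky
factor of the local covariance and ξ iid standard normal, independent across
snapshots and reproducible from the spec seed. Default: 25 snapshots at 15 ms
intervals (the midpoints of the 20–30 snapshot / 10–20 ms ranges typical of
this acquisition-simulation design). Gaussian, temporally uncorrelated
fluctuations are consistent with the Gaussian intravoxel assumption of the
MRI model itself; real turbulence has spectra and spatial coherence this
fixture does not attempt to reproduce. Consequently, passing tests show that
the *measurement chain* behaves as expected under its own assumptions — they
do not validate the chain against non-Gaussian, spatially coherent real
flows.

**Domain.** The full profile is defined on [−4 D, +21 D]; the default
generated window is [−2 D, +6 D], which contains the convergence, the jet and
its entire turbulent region — the omitted far outflow is recovered laminar
pipe flow that adds only memory and runtime. Any sub-interval of the full
domain can be requested.

## Acquisition simulation

Voxelisation uses an isotropic Gaussian kernel with σ = Δz/2.35 truncated at
3σ (≲0.3% of kernel mass discarded), normalised over lumen samples only.
Two equivalent evaluation paths exist on purpose:

* per-voxel scattered-sample operations (Euclidean-ball truncation, 64-bin
  histogram of the intravoxel distribution spanning ±VENC) that follow the
  definitions literally and are used as test oracles;
* a separable-convolution volume path: because the weighted voxel sum of any
  sample quantity is linear, per-voxel sums of cos/sin(k_v e·v) accumulated
  over snapshots are a Gaussian filter of the fine-grid fields, sampled at
  voxel centres with cubic interpolation. This path evaluates the signal from
  the *unbinned* empirical distribution (no histogram error) and uses
  per-axis (box) truncation at 3σ. The two paths agree within ~2% locally in
  the sharpest shear layers and far better elsewhere.

The directional mean velocities are Gaussian-weighted averages over all
snapshots and kernel samples (the phase channel of the measurement); the
directional IVSDs come from the signal-magnitude model. The scaling constant
C is arbitrary in the physics and fixed to 1. VENC defaults to
1.2 × (max mean speed + 3 × max fluctuation std) — deterministic in the
phantom statistics — and no phase wrapping is simulated. SNR uses the 3σ
convention with a single global reference per channel class (VENC for
velocity, C for signal); noise is applied only on valid (lumen) voxels, and
one noise-free encode is reused across noisy repetitions.

Voxels are valid where the kernel-weighted lumen fraction ≥ 0.5 (threshold
configurable); valid voxels with fraction < 0.99 carry a partial-volume flag.

## IVSD clipping versus signed variances

The physical IVSD estimator σ_i = √(2 ln(|S(0)|/|S_i|))/k_v is undefined when
noise drives |S_i| ≥ |S(0)|; `estimate_ivsd` returns 0 with a `clipped` flag
so downstream sums stay finite. However the Reynolds-*tensor* solve consumes
directional **variances**, and there the package uses the signed quantity
(2/k_v²)·ln(|S(0)|/|S_i|), which may be negative. The reason is statistical:
the log-magnitude of a complex signal under Gaussian channel noise is
unbiased to leading order, so signed variances propagate zero-mean noise into
the tensor, whereas clip-at-zero asymmetrically inflates weak encoding
directions, isotropises the tensor, and systematically shrinks the production
term (observed at the tens-of-percent level at SNR 20 on the default
phantom). The signed square-sum's noise robustness — the central claim this
package quantifies — requires the signed path, and the negative-diagonal
flagging of reconstructed tensors anticipates exactly these excursions.
Clipped IVSDs remain what TKE-from-IVSD and any per-direction reporting use.

## Stress maps

Velocity gradients use second-order central differences, with one-sided
second-order (three-point) closures at lumen-mask boundaries, first-order
two-point stencils where only one neighbour exists, and a flag for isolated
voxels. Trace(S) on the reconstructed fields is ~5% of the strain magnitude
(discretisation), so isotropic tensor-noise contributions to production
nearly cancel.

Maximum principal shear uses the closed-form trigonometric eigenvalue
solution for symmetric 3×3 tensors with the arccos argument clipped to
[−1, 1]; degenerate spectra are benign for the (λ_max − λ_min)/2 invariant.
It is verified against `numpy.linalg.eigvalsh` and a characteristic-
polynomial root solver to 1e-9.

TVSS is √(prefactor·μ·P) with the prefactor isolated in one module constant
(set to 1, i.e. TVSS = √(μρε) with ε = P/ρ). Voxels with P < 0 are flagged
undefined and excluded from the flagged TVSS sum; the signed square-sum
Σ sign(P)|μP| dV is defined everywhere and retains negative-production signs,
which is the interpretation of "including all noise components regardless of
sign" adopted here (the flagged alternative remains available through the
TVSS map itself). Note that even noise-free acquisitions produce some
negative production at the nozzle: partial-volume variance from strong mean
gradients contracts with the accelerating strain — an artifact inherent to
the Gaussian intravoxel model, present in any such simulation.

## Blood damage index

Pathline seeds are drawn uniformly over the inlet disk (default radius
0.95 R₀, 2000 seeds); integration is classical RK4 with trilinear
interpolation on the voxel grid (velocity zero outside the valid lumen) and a
fixed default step of 0.5 ms. Lines terminate at the outlet plane, on leaving
the domain, after 50 consecutive steps below 10⁻⁴·U_bulk, or at the step cap
(pipeline default 6000, enough for ≥99% completion on the default phantom;
the tracer itself allows up to 10⁶ with geometrically grown buffers). The
stress along each line is sampled at the start of every step.

The damage recursion D_k = D_{k−1} + τ_k^{b/a}Δt,
ΔBDI_k = C·a·D_k^{a−1}·τ_k^{b/a}Δt (a = 0.785, b = 2.416, C = 3.62×10⁻⁵;
D₀ = 0) reproduces the closed form C τ^b t^a for constant stress with a
convergence order equal to the time exponent a ≈ 0.785 — the t^a endpoint
behaviour, not the integrator, limits the rate — giving −0.22% error at
Δt = 1 ms over 1 s. In squared-stress mode (default) every τ power is
evaluated through the signed squared-TVSS sample, τ^p ≡ q^{p/2} for q > 0 and
zero otherwise; this is an interpretation of "using the square of TVSS" in
the damage model, chosen for consistency with the signed square-sum, and the
plain flagged-TVSS source remains selectable. The outlet summary is the
median (plus quartiles) over lines that reached the outlet; non-completing
lines are excluded from the median and counted in diagnostics.

## Evaluation sweeps

The resolution sweep runs the noise-free chain per case and voxel size
(defaults: 1.0–3.0 mm at 0.2 mm) and pairs volumetric sums against
ground-truth sums computed directly from the fine-grid phantom fields.
Agreement uses ordinary least squares (statsmodels) and Bland–Altman
differences oriented simulated − truth with mean ± 1.96 SD limits. The
default case grid is 2 severities × 1 PSD × 3 Reynolds numbers; the full
severity × PSD × Re grid is available through configuration.

The SNR sweep (default levels {2, 5, 10, 20, 40, 80, ∞}, ten repetitions)
reuses one noise-free encode, normalises every metric to its own noise-free
value (the ∞ rows are exactly 1), and derives repetition seeds as
base_seed + index, shared across levels so each repetition sees paired noise
draws. The pathline/BDI metric can be restricted to a subset of levels since
it dominates runtime.

Problem sizes in the test suite and acceptance script are desk-scale by
design: the default [−2 D, +6 D] phantom window at 0.25 mm (about 1.9M fine
cells), 25 snapshots, 1 mm voxels, ten repetitions per SNR level and 2000
pathlines; the resolution-trend checks use a [−1.2 D, +3 D] window over a
2 × 2 case grid at 1 and 3 mm.

## Known limitations

* The phantom's turbulence is Gaussian, temporally white and prescribed, not
  solved; spectra, intermittency and coherent structures are absent.
* The mean field is a parametric jet model: no recirculation velocity in the
  separation zone (it is quiescent), a kinked profile radius where the jet
  re-attaches, and no pulsatility.
* MRI artifacts beyond noise and partial volume (wrapping, eddy currents,
  concomitant fields, signal voids, k-space truncation) are out of scope.
* Stress interpolation along pathlines is trilinear; near-wall damage
  accumulation is resolution limited, as in the imaging method itself.
* The hemolysis power law itself is taken as given; nothing here validates
  its coefficients against blood experiments.
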