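# Methods

This note documents the model, the numerics, and the design choices made
where the formulation left genuine freedom. Everything quantitative stated
here is computed by the test suite or by `scripts/acceptance.py`.

## Model and assumptions

The membrane patch is a single homogeneous elastic sheet with bending
rigidity κ (default 20 k_BT, the consensus scale for cytoskeleton-free
plasma membrane) and frame tension σ (default 0), treated in the Helfrich
continuum description. Gaussian-curvature elasticity is omitted: for
shape changes at fixed topology its integral is constant. Thermal
fluctuations and entropic corrections are neglected, as is everything
kinetic — coat nucleation/growth, scission, and protein exchange are out
of scope; each solved shape is an equilibrium configuration under a
prescribed protein field.

Axisymmetry is assumed throughout. The shape is parameterized by the
tangent angle ψ(s) of the meridian as a function of arc length s from the
pole, with R′ = cos ψ and z′ = sin ψ. This parameterization represents
overhangs (ψ > π/2) without special-casing, which is essential: mature
buds are strongly overhung. The patch is pinned at its rim, R(s₁) = R₀ =
500 nm with ψ(s₁) = 0, representing cytoskeletal confinement of the
coat-containing membrane domain; the total arc length s₁ is free.

Curvature convention: H = ψ′ + sin ψ / R is the *sum* of the principal
curvatures (sphere of diameter d: H = 4/d; tubule of diameter d: H =
2/d). All spontaneous-curvature amplitudes in the package are on this
scale: the single-epsin peak C₀ = 0.1 nm⁻¹ corresponds to the 20-nm
tubules epsin generates in vitro, and the capsid plateau 0.08 nm⁻¹ to a
preferred 50-nm sphere.

The minimized objective is E = ∫ [(κ/2)(H − H₀(s))² + σ] dA with the
constraint term ∫ γ(s)(R′ − cos ψ) ds defining R. Two energies must not
be confused:

* the **objective** (reported by `functional_energy`), measured against
  the imposed field H₀ — it is small for a compliant shape;
* the **deformation energy** E_c = (κ/2)∫ H² dA (`deformation_energy`),
  measured against the flat state — this is the bending cost the protein
  machinery must pay, and the quantity reported throughout. On a closed
  sphere E_c = 8πκ independent of radius.

## Spontaneous-curvature fields

* `single_epsin_field`: H₀(s) = C₀ exp(−(s−c)²/b²). The Gaussian width
  convention (no factor 2 in the denominator) is fixed and documented
  because b is a calibrated, convention-dependent quantity.
* `shell_field`: additive superposition of such Gaussians centered at arc
  positions 0, 18.5, 37, ... nm — concentric epsin rings templated by the
  clathrin lattice, whose vertex spacing (18.5 nm) sets the shell spacing
  along the membrane.
* `capsid_field`: H₀ = 0.08 nm⁻¹ for s < s₀ and 0 for s ≥ s₀
  (right-open step), the simplest stand-in for the collective field.

Shells carry unit amplitude C₀ each (the field of a templated ring), not
an amplitude weighted by the ring's epsin count; the epsin count enters
the energetics, not the curvature field.

## Numerical scheme

**State and propagation.** Internally the solver propagates
(ψ, U, R, z, g) with U = H − H₀ and g = γ R₀/(2πκ): stationarity gives
U′ = g sin ψ / R and g′ = U²/2 + σ̃ − U sin ψ / R. Working in U has two
payoffs: the equations contain no dH₀/ds term, and U is continuous across
discontinuities of H₀ (where ψ′ jumps by the step in H₀, the capsid
edge), so the step field needs only an integrator restart at s₀, no jump
handling in the state. Lengths are scaled by R₀ and energies by κ, so at
σ = 0 the dimensionless system is κ-free — shapes are exactly
κ-independent and E_c is exactly linear in κ, which the tests assert.

**Pole.** The R = 0 coordinate singularity is regularized by a
leading-order series start at s = ε = 10⁻³ nm: ψ ≈ a s, R ≈ s, with pole
curvature H(0) = 2a. Halving ε moves the solution by < 10⁻⁸ (test).

**Shooting.** Unknowns (a = ψ′(0), γ₀, s₁); residuals (ψ(s₁),
R(s₁) − R₀, 𝓗(s₁)), where 𝓗 is the first integral of the system — its
vanishing at the free endpoint is the closure condition that determines
s₁. Integration uses an adaptive 8th-order explicit Runge–Kutta scheme
(rel/abs tolerances 10⁻⁸/10⁻¹⁰) with termination events on R ≤ 0 and
|ψ| > 2π; root finding uses a hybrid Powell method with finite-difference
steps set well above integrator noise, converged when the residual norm is
below 10⁻⁸. Failed shots (trajectories leaving the physical domain) are
returned as penalized residuals, not crashes.

**Continuation.** Post-critical overhung branches are unreachable by cold
shooting, so every hard solve is a march: the field amplitude, the capsid
extent s₀, or the fractional amplitude of a newly added shell is ramped
in steps of 1/20 (halved on failure down to 1/320, doubled back on
success), each converged shot warm-starting the next. A
`ContinuationFailure` reports the last reached fraction; past complete
bud closure (the neck radius → 0) no solution exists and the failure is
the physically correct answer.

**First-integral check.** Where H₀ varies, 𝓗 is not conserved but obeys
d𝓗/ds = 2πκ R U dH₀/ds (plus point jumps 2πκ R U ΔH₀ at steps). The
solver integrates this source alongside the final pass;
`hamiltonian_residual` subtracts it and the corrected residual is below
10⁻⁵ k_BT/nm on all converged profiles (tests assert 10⁻⁴).

**Quadrature.** Profiles are sampled on ~4000 points, three quarters of
them concentrated over the field's footprint; energies and areas use
trapezoidal quadrature on that grid. Doubling the grid or halving the
integrator tolerances changes E_c by < 0.02% (tests assert 0.1%).

**Independent oracle.** The test suite contains a from-scratch direct
minimization of the discretized functional (ψ on a uniform grid, R by
cumulative integration, rim pinning by quadratic penalty, analytic
gradient, L-BFGS) started from an analytic spherical-cap guess. For the
capsid field at s₀ = 25 nm it reproduces the shooting solution's E_c to
0.03% (asserted < 1%), checking the variational content of the shape
equations against generic optimization.

## Energetics layer

**Epsin census.** One epsin sits at the pole; each ring at arc position
s₀ᵢ holds 2πR(s₀ᵢ)/18.5 epsins (circumference at the lattice spacing).
Real-valued totals are kept; printed comparisons round to nearest. The
CLAP-cell mature-vesicle count uses the observed 1.6× area ratio with
floor rounding: floor(21 × 1.6) = 33.

**Range calibration.** b is fixed by requiring that the deformation
energy of the membrane under a *single* epsin equal the 14 k_BT magnitude
of the ENTH binding energy (bracketing root search in b, each evaluation
a full continuation solve; E_c(b) is monotone over the bracket). At
κ = 20 k_BT this yields b = 9.50 nm. Both Gaussian width conventions
were examined; under the alternative exp(−x²/2b²) convention the same
physics corresponds to b = 6.72 nm. The calibration is re-run per κ in
the rigidity sweep (b ≈ 13.5 nm at 10 k_BT down to 6.0 nm at 50 k_BT);
since E_c ∝ κ at fixed shape, stiffer membranes balance at narrower
footprints.

**Maturity and classification.** A bud is *mature* when it is overhung
(max ψ > π/2) and its neck has constricted to ≤ 35% of the maximal bud
radius. The threshold reads "narrow neck" as narrower than about a third
of the bud radius: the capsid model's overhung constricted-neck shape at
s₀ = 70 nm sits at ratio 0.335 and its wide-necked s₀ = 50 nm
intermediate at 0.91, so any threshold between those separates the two
regimes; 0.35 includes the former with margin. Categories: 1 if the bud
depth is < 10% of the coat extent (near-planar); else 2 if the bud
diameter does not exceed the neck diameter (shallow cap); 4 if mature;
3 otherwise. Both thresholds are configurable (`MaturityRules`).

**Coat-extent sweeps.** The coat extent s₀ is the continuous sweep
variable for both models. For the shell model a ring is present at every
lattice multiple not exceeding s₀, and A_a = 2π∫₀^{s₀} R ds and the neck
radius R(s₀) vary continuously between ring completions; the sweep
reports the first mature grid point and a bisection-refined critical coat
area. Rows where the nominal coat would extend past the neck of an
overhung bud are dropped (a coat beyond the neck is geometrically
meaningless), and if a ring cannot assemble at all — the bud closes
completely while it is ramped in — larger extents are evaluated on the
largest assembled-ring configuration. In the rigidity sweep, when no
complete-ring state constricts below threshold (observed at κ = 30 k_BT,
where the 4-ring branch bottoms out at ratio 0.39 and the 5-ring branch
terminates at a fold), the sweep refines along the partial-ring branch
and, failing that, reports the last pre-fold state flagged
`fold_snap` — the bud there snaps from a ~0.39 neck ratio toward closure
as the ring completes.

**Boltzmann distribution.** E_t(A_a) = E_c + E_a + E_r on the capsid
ladder s₀ = 10–80 nm in 5-nm steps (extents past complete closure are
skipped and logged). E_a = −20 k_BT, the assembly free energy of the
closed clathrin/AP-2 basket, taken constant in A_a (pluggable via
`EnergyParams.E_a_fn` for sensitivity analysis). E_r uses the smooth
lattice-cell density N(A_a) = max(1, A_a/18.5²) — the area-continuous
form of the ring census, with which it agrees at complete-ring
configurations (22.3 vs 21.9 at the mature capsid bud) — times the
per-epsin energy: −23 k_BT (ENTH −14 plus CLAP −9) in wildtype, −14 k_BT
with the CLAP–clathrin interaction abrogated. A staircase census would
imprint ~100 k_BT sawteeth on E_t that Boltzmann weighting amplifies into
artifacts; the density rule is the choice consistent with the same
per-area epsin coverage in both scenarios. With it, wildtype E_t falls
monotonically with coat area (mature category-4 buds dominate,
P₄ ≈ 0.91) and the CLAP scenario rises monotonically (early
intermediates dominate) — the knockout reverses the distribution.

## Defaults

| parameter | default | units | meaning |
|---|---|---|---|
| κ | 20 | k_BT | bending rigidity (sweep 10–50) |
| σ | 0 | k_BT/nm² | frame tension |
| R₀ | 500 | nm | pinned patch radius |
| C₀ | 0.1 | nm⁻¹ | single-epsin peak curvature |
| b | calibrated (9.50 at κ=20) | nm | epsin Gaussian range |
| spacing | 18.5 | nm | clathrin lattice periodicity |
| capsid H₀ | 0.08 | nm⁻¹ | step-field plateau |
| ε_ENTH, ε_CLAP | −14, −9 | k_BT | per-epsin binding energies |
| E_a | −20 | k_BT | coat assembly free energy |
| neck ratio | 0.35 | — | maturity threshold |

## Problem sizes

Default runs solve on ~4000-point output grids with ladders of 15 coat
extents (distribution), ~15 extents with ≤ 8 rings (shell sweep) and 5
rigidities (κ sweep); the full test suite and the acceptance script each
complete in a few minutes on one CPU. These sizes leave all reported
quantities mesh-converged (see above); they are package defaults, and all
grids are configurable.

## Known limitations

* Axisymmetric, fixed-topology shapes only; no scission, no neck beyond
  the continuum's validity (~bilayer thickness), no neighboring coats.
* The model states are energy minima under a *prescribed* field — there
  is no assembly kinetics, so "growing the coat" means marching a
  parameter, and fold terminations are interpreted, not simulated.
* E_a's area-dependence is unknown; the constant default matters little
  (|E_c| ≫ |E_a|) but is untested against data.
* σ ≠ 0 is exposed and solvable but no quantitative claims are made for
  it; shooting becomes stiffer as σ grows (exponential far-field modes).
* The four-category classifier is a declared reconstruction validated
  only through the qualitative wildtype/CLAP ordering reversal; the
  category-1/2 boundary in particular is a convention.
* The self-consistently calibrated b = 9.50 nm at κ = 20 k_BT makes the
  mature shell-model bud somewhat smaller (critical A_a ≈ 5.9–6.1 × 10³
  nm², ~18.5 epsins) than the same pipeline run with b = 8.3 nm
  (A_a ≈ 6.4 × 10³ nm², ~22 epsins); all downstream shell-model numbers
  inherit this sensitivity to the calibration constant.
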