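# Methods

## Model

The package solves the dimensionless boundary-layer system for an
electrically conducting Casson nanofluid (human blood as base fluid, single-
or multi-walled carbon nanotubes as particles) next to a vertical plate in a
porous medium under a transverse magnetic field:

```
CPC_t^α u = A u_ξξ − L u + C θ,      CPC_t^α θ = F θ_ξξ,
```

with u = θ = 0 initially, u(0,t) = H(t)cos(Qt) and θ(0,t) = 1 at the wall
for t > 0, and zero far-field values imposed at a finite truncation length l.
The model assumes thermal equilibrium between particles and base fluid, no
slip, constant properties, and linear (Boussinesq-type) buoyancy coupling;
velocity does not feed back into temperature, so the system is lower
triangular in (θ, u).

Mixture constants: φ₁ = (1−φ)^2.5·[(1−φ) + φ·ρc/ρf] (Brinkman viscosity
combined with the mixture density), φ₂ from the Maxwell electrical-
conductivity rule, φ₃ and φ₄ linear volume-weighted mixtures of (ρβ) and
(ρCp), and φ₅ = k_nf/k_f from the Xue logarithmic model, which is the
appropriate mixture rule for high-aspect-ratio CNTs.  All five reduce to 1
at φ = 0 for any property ratios, and the code asserts positivity and
finiteness.  At k_c = k_f the Xue expression is 0/0 with limit exactly 1; the
code switches to the limit when |k_c − k_f| ≤ 1e−12 relative.

The drag constant is implemented as L = M·φ₂ + φ₁/K: a Darcy drag must decay
with increasing permeability K, and the monotonicity tests enforce exactly
that.  The alternative product reading (φ₁·K) remains selectable
(`drag_form="product"`) because the source expression for L is ambiguous.

Material presets (SWCNT-blood, MWCNT-blood, neutral) ship in a YAML file with
literature property values; every quantitative experiment supplies its ratios
explicitly so no result depends on the preset file.

## The CPC operator and its two RL conventions

CPC_t^α f = K₁(α)·(RL part) + K₀(α)·(Caputo part) with K₀ = αS^(1−α),
K₁ = (1−α)Sᵅ.  The kernel scale S is "the value of time in the numerical
solution"; we default S to the final simulation time T and allow an override.
At α = 1, K₀ = 1 and K₁ = 0 and the solver provably collapses to the
classical θ-scheme (tested to 1e−10 against an independent classical
stepper).

The operator's definition uses an RL *integral* I^(1−α), but the scheme it
feeds is written with a GL *derivative* of order 1−α.  Both are implemented
behind `rl_convention`:

* `as_printed` (default): RL derivative, prefactor K₁/φ(Δt)^(1−α), GL weights
  of order 1−α.  The assembled scheme and the stability constants use this.
* `integral_consistent`: GL quadrature of I^(1−α), prefactor K₁·φ(Δt)^(1−α),
  GL weights of order −(1−α).  Verified against the closed form
  I^(1−α)1 = t^(1−α)/Γ(2−α) on refinement.

GL weights are generated by the recursion W_k = (1 − (β+1)/k)W_{k−1} (stable
for large k) and cross-checked against the Γ-function binomial form to 1e−12
for k ≤ 30.  The Caputo term uses the L1 rule with weights
z_k = (k+1)^(1−α) − k^(1−α); z₀ is set to 1 explicitly so the α = 1 limit is
the exact first difference (the naive expression would evaluate 0⁰).  The L1
rule is exact for linear-in-time data, which the tests assert at 1e−12.

## Discretization

Space: 3-point (1,−2,1)/ψ(h)² or 5-point compact
(−1/12, 4/3, −5/2, 4/3, −1/12)/ψ(h)² stencils; the compact stencil is exact
for quartics and carries formal order 4.  Near the boundary the 5-point rows
need a closure; the default `fallback2` substitutes the 3-point stencil at
the first and last interior node (keeps the operator pentadiagonal; degrades
the formal order only in an O(h) neighbourhood), and a `ghost` closure based
on odd reflection through the boundary value is available.

Time: the stencil term is split ω-explicit / (1−ω)-implicit (ω = 0 fully
implicit, ω = ½ Crank–Nicolson-type, ω = 1 explicit); drag −L·u and the
buoyancy coupling +C·θ enter explicitly at the old level, exactly as the
scheme is written — no implicit-coupling variant is offered.  Temperature is
advanced before velocity inside each step, so velocity consumes a final
θ-level.  Each step solves

```
[f·I − D(1−ω)·S] x^{j+1} = known terms,   f = K₀·Δt^(1−α) / (φ(Δt)·Γ(2−α)),
```

a time-independent pentadiagonal system factored once per run
(scipy sparse LU); the Caputo and RL history sums enter the right-hand side,
giving O(Z²N) total cost (full history, no short-memory truncation).  The
run is bit-for-bit deterministic.

Corner condition: the zero initial state owns the corner (ξ, t) = (0, 0); the
wall values apply from the first time level on.  Manufactured sources are
evaluated only at levels whose ω-weight is nonzero, because the fractional
steady-state source carries a t^(α−1) singularity at t = 0.

## Nonstandard denominators

Three named pairs:

* `standard`: φ(Δt) = Δt, ψ(h) = h.
* `nonstandard`: φ(Δt) = 0.001(1 − e^(−Δt)), ψ(h) = 0.5·sinh(h/2) — the pair
  the published nonstandard experiments state.  This pair violates the
  Mickens consistency requirement φ(Δt) = Δt + O(Δt²): φ ≈ Δt/1000 and
  ψ ≈ h/4 for small steps, which inflates the Caputo mass factor f by ~10³
  and makes the scheme dramatically under-diffusive (see Limitations).
* `nonstandard-consistent`: φ(Δt) = 1 − e^(−Δt), ψ(h) = 2·sinh(h/2), a
  conforming Mickens pair provided for meaningful nonstandard runs.

## Exact reference solutions

For the classical model (α = 1), Q = 0, the temperature is
θ = erfc((ξ/2)√(b₀/t)) with b₀ = Pr·φ₄/φ₅ = 1/F, and the Gr = 0 velocity is
the damped-diffusion pair of exponentially weighted erfc terms with
a₁ = 1/A and drag L.  Both are verified to solve their PDEs by high-order
numerical differentiation: max residual ≤ 1e−6 over a 5×5 (ξ, t) lattice for
three parameter sets (≈1e−10 in practice), with wall values exactly 1.  The
printed b₀ in the source expression is typographically corrupted; b₀ = 1/F
is forced by requiring the temperature expression to solve its own equation
(residual-verified).  The buoyancy amplitude b₁ of the Gr ≠ 0 branch is a
reconstruction (a₁·Gr·φ₁·φ₂/(b₀−1), overridable); all quantitative
validation is restricted to Gr = 0, which covers every error-table
configuration.  These solutions are the α-independent reference of every
error table: for α < 1 the reported "error" therefore mixes discretization
error with the genuine fractional-vs-classical model difference, exactly as
in the experiment design the harness reproduces.

## Stability analysis

Because the system is lower triangular with bounded explicit coupling,
stability is assessed per scalar field (temperature: diffusivity F, no drag;
velocity: A and L; the coupling C·θ is a bounded source).  A Fourier mode
gives

```
η = [2Z₁cos2qh + 2Z₂cosqh + Z₃ + f·Σ z_k χ^(−k) − s·Σ W_k χ^(−k)]
    / [2A₁cos2qh + 2A₂cosqh + A₃ + f·Σ z_k χ^(−k)],
```

where the A/Z constants are extracted to agree exactly (tested to 1e−10 over
an (ω, α, field) lattice) with the Fourier symbol of the assembled step
matrices; the commonly printed closed-form constant table for this scheme has
inconsistent signs on its stencil blocks and drops the Δt^(1−α) factor in the
mass term, so the assembled scheme is taken as ground truth and the printed
table is not reproduced verbatim.  The constant s is read as
K₁/φ(Δt)^(1−α) (a ψ/φ typo in the printed form), consistent with the RL
prefactor of the scheme itself.

The history ratio χ is not constant in a genuine multi-level scheme.  Two
treatments: `unit_modulus` (default) freezes |χ| = 1 — a non-decaying-history
bound — and `fixed_point` iterates χ ← η to self-consistency (tolerance
1e−10, ≤ 200 iterations, falling back to the bound with a warning).
Crucially, the scan takes the maximum of |η| over a geometric ladder of
history lengths 1..m as well as over the phase range (0, π]: the Caputo
history sum grows like j^(1−α), so the damping mass is smallest in the early
steps and a long-history-only scan can miss violent transient growth (we
observed exactly this for the explicit scheme at small Δt).  A mode is
declared stable when max|η| ≤ 1 + 1e−9.

The scan verdicts are validated against behaviour: on a 3×3 (ω, Δt) lattice
(ω ∈ {0, ½, 1}, Δt ∈ {0.0005, 0.01, 0.08}, h = 0.2, α = 0.8, error-table
parameters) a 200-step run from a seeded random initial field in [−1, 1] with
homogeneous boundaries must stay within 10× its initial magnitude exactly
when the scan says stable.  The lattice spans both regimes (implicit/CN
always damping; explicit stable only at the smallest step) and the agreement
is 9/9.

## Manufactured verification and the spatial-order experiment

A manufactured steady profile v(ξ) (quadratic or Gaussian) is held exact by
adding the source g(ξ,t) = K₁·v·t^(α−1)/Γ(α) + L·v − D·v″ (the closed-form
CPC derivative of a time-constant field under the default convention).  With
the profile as initial and boundary data the discrete Caputo term vanishes
identically, so the remaining error isolates the spatial stencil plus the
(small, O(1/Z)) GL-vs-closed-form history quadrature mismatch.  The quadratic
profile is held to round-off by both stencils (they differentiate quadratics
exactly); the Gaussian profile (center l/2, width 0.5 on l = 5) drives the
observed-order study: error-table parameters, α = 0.95, standard
denominators, fully implicit, Z = 1000 steps to T = 0.9, grids N = 20 vs 40.
Measured orders: ≈ 3.93 for the compact stencil and ≈ 2.04 for the 3-point
stencil (the acceptance thresholds are 3.9 and 1.9).  These sizes were chosen
so the spatial error dominates the history-quadrature bias by two orders of
magnitude while the whole study runs in about a second.

## Experiment fixtures

The published error tables state parameters but not grids; fixtures default
to l = 5, N = 50, Z = 90 so every probe position (ξ ∈ {2, 2.4, …}) is a grid
node and every evaluation time a grid level.  Errors are reported as absolute
values at probe nodes with no interpolation, and order columns are truncated
(not rounded) to two decimals, matching how the published tables print.
Table 6's parameter set is unstated; its fixture reuses the Table-2 set, and
the published (e_M, e_2M) maximum-error pairs ship as fixture data so the
order-formula consistency check is self-contained.

## Known limitations and non-reproduced claims

* The published error tables cannot be matched digit-for-digit (grids
  unknown); the harness reproduces properties, not digits.
* The published accuracy ranking (nonstandard-compact best) does **not**
  reproduce under a faithful implementation: with the stated nonstandard
  denominators the scheme is ~10³× under-diffusive and its probe errors
  equal |u_exact| itself, and even with the conforming pair the probe error
  is dominated by the α-model-vs-classical-reference difference, which the
  denominator perturbation slightly increases.  The corresponding acceptance
  test asserts the published ranking and is expected to fail; the measured
  max errors of all three schemes are reported by the acceptance script.
* In the boundary-driven Gr = 0 regime, velocity at fixed ξ *increases* with
  the volume fraction φ (raising φ raises the effective momentum diffusivity
  A), contrary to the published inverse claim; the γ- and M-monotonicities do
  reproduce and are the tested sweep properties.
* No short-memory acceleration: runtime grows as O(Z²N).  No nonuniform
  grids, no implicit coupling, no exact solutions for Q ≠ 0 or for the
  fractional operator itself, and no dimensional analysis (M, K, Pr, Gr are
  consumed dimensionless).
* The synthetic experiments exercise smooth manufactured fields and random
  bounded initial data on truncated domains; passing them demonstrates
  correctness of the discrete operators and stepping, not fidelity of the
  physical model to real hemodynamics.
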