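# Methods

## Model

`cpcphase` simulates the setting of injectable calcium-phosphate cement
paste as a non-conserved phase-separation process. The order parameter
φ(t, x, y) on Ω = [−L, L]² encodes the local paste state (1 solid, 0 void,
0.5 liquid) and obeys

    φ_t = D(t) Δφ + ε⁻² f(φ),   f(φ) = φ(1 − φ)(φ − φ̄),

with homogeneous Neumann (zero-flux) boundaries: the square is a small
interior patch of a 2-D slice through the cement cylinder, so its boundary
is mathematical, not physical. Model assumptions, in the package's terms:

* **Setting is diffusion with a deadline.** D(t) is the exact two-valued
  step D₀·1{t < T}: diffusion (material transport during setting) acts at
  full strength until the initial-setting time T and then stops. T is the
  model counterpart of the Vicat-needle setting time (first measurement
  with 0 mm penetration), and the step shape mirrors the abrupt arrest the
  needle test shows. No smoothing is applied; smoother interpolations of
  the same data would change details but not the qualitative outcome, and
  the step keeps the switch analytically clean.
* **Phase competition with a concentration-dependent bias.** The cubic
  reaction drives φ to the stable states 0 (void) and 1 (solid); its
  unstable root φ̄ is the solid-formation threshold. φ̄(c) = 0.5/(1+c/1000)
  decreases with IP6 concentration: IP6-modified powder disperses better,
  making solidification win more territory. For φ̄ < 0.5 the solid well of
  the potential W (with W′ = −f) is deeper: W(1) = φ̄/6 − 1/12 < 0.
* **Scale transform.** Under the proportionality T(c) ∝ ε(c)², the
  substitution t = λτ, x = √μ ξ with λ = ε²/ε₀² = T/τ₀ and μ = (D₀/d₀)λ
  maps any parameter triple onto a reference (d₀, τ₀, ε₀), so all
  concentration dependence collapses into φ̄(c). The two expressions for λ
  must agree to relative 1e−12; a mismatch raises an error rather than
  being silently reconciled, because the proportionality is a modelling
  assumption whose violation should be visible.
* **After the switch, cells decouple.** For t ≥ T each grid value evolves
  by the scalar ODE φ′ = ε⁻²f(φ): values above φ̄ rise monotonically
  toward 1, values below fall toward 0. Void regions present at T can
  therefore only deepen, never heal; all healing happens while diffusion
  is active. This is why, on the snapshot grid {0.2, …, 1.0} with T = 0.8,
  a run in which voids vanish shows the vanish at the 0.8 snapshot.

## Key parameters

| parameter | default | meaning |
|---|---|---|
| D₀ | 0.01 | diffusion magnitude while setting (dimensionless after scaling) |
| T | 0.8 | switch-off (initial-setting completion) time |
| ε | 0.1 | phase-separation strength; ε⁻² multiplies the reaction |
| c | 0 | IP6 concentration; enters only through φ̄(c) |
| φ̄ | 0.5/(1+c/1000) | solid-formation threshold; explicit override supported |
| L, N | 1, 200 | domain half-width and grid points per side, h = 2L/N |
| Δt | 0.1/N² | RK4 step (reproduction default) |
| noise | 5% of h | uniform, symmetric, per-cell amplitude of the initial perturbation |

All defaults together constitute the reference run; an empty TOML config
reproduces it exactly.

## Numerics

* **Space.** Cell-centered N×N grid (centers at −L + h/2 + i·h), 5-point
  Laplacian. Neumann boundaries by mirrored ghost cells (ghost equals the
  adjacent interior value), which is exactly the zero-normal-derivative
  condition for fields even about the boundary and second-order otherwise.
  Cell-centering makes h = 2L/N exact and the mirror trick clean; a
  node-centered variant is deliberately not offered.
* **Time.** Classical RK4 with fixed Δt. The step sequence is snapped so
  that the switch time T, every snapshot time and t_end are step
  boundaries (the last step of each segment is shortened); snapshot times
  are reconstructed from the segment boundaries rather than accumulated,
  so they are hit exactly. Within a step all four stages use the diffusion
  value of the regime the step starts in — the one-sided limit valid on
  the whole step — so the scheme is plain RK4 on each smooth piece and no
  stage samples the discontinuous coefficient across the jump. A step that
  would straddle T is refused, not silently split.
* **Step-size policies.** `fixed` uses the supplied Δt (default 0.1/N²,
  the very conservative reproduction value). `stability-checked` validates
  Δt ≤ min(h²/(4D₀), 0.1·ε²): the first factor keeps the extreme diffusion
  eigenvalue (≈8D₀/h²) well inside the RK4 stability interval, the second
  resolves the fastest reaction rate (≈ε⁻²/4) with a 10× margin. Most of
  the test suite runs at this faster step.
* **Diagnostics, not clamps.** NaN/Inf aborts the run with the offending
  time interval; values are never clipped during integration (clipping
  happens only in PNG rendering). `OrderParameterField.range_violation`
  reports excursions outside [0, 1] beyond 1e−6.
* **Energy.** E = (D/2) Σ_faces (φ_a − φ_b)² + ε⁻² h² Σ W(φ) is the exact
  discrete Lyapunov functional of the semi-discrete system: the
  method-of-lines ODE is its gradient flow, so E is non-increasing on
  every interval of constant D. Tests assert this step-by-step (tolerance
  1e−10). E can be negative when φ̄ < 0.5 (deep solid well); monotonicity,
  not sign, is the meaningful property.
* **Floating-point exactness.** The stencil is summed as
  (E+W) + (N+S) − 4C so a uniform field has an exactly zero Laplacian, and
  the reaction vanishes identically at 0, φ̄, 1; the uniform states at the
  cubic's roots are therefore bit-stable fixed points of the integrator.
* **Performance.** The RK4 segment loop is compiled with numba (boundary
  columns peeled out of the hot loop); a vectorized numpy fallback with
  identical arithmetic is used if numba is unavailable. The reference
  N = 200 run (400 000 steps) takes ~70–90 s on one CPU.

## Initial conditions

`noisy_uniform_field` draws per-cell i.i.d. uniform noise on
[−0.05h, +0.05h] around φ₀ = 0.5 from a counter-based (Philox) stream in
row-major order, so a (seed, N, L) triple gives a bitwise-reproducible
field on any platform. The "5% of h" convention (amplitude, uniform,
symmetric) is a choice — only the 5%-of-h magnitude is prescribed — and is
recorded in every run manifest. `boundary_set_field` optionally seeds
setting from the domain rim (set cells within a given distance of ∂Ω to a
rim value), emulating setting that starts at the boundary.

The generator emulates injection-induced coarseness/density fluctuations
as white noise. It does not reproduce spatially correlated texture, the
real paste's particle-scale granularity, or any boundary-driven onset
present in experimental images; passing tests therefore validate the
model's response to idealized perturbations, not quantitative agreement
with micrographs.

## Void metrics

Cells are labeled void (φ ≤ θ_void), solid (φ ≥ θ_solid) or intermediate,
with defaults (0.1, 0.9) — bands symmetric about 0.5 are required because
the ideal phases 0 and 1 are reached only asymptotically. A counted void
is a 4-connected component of at least `min_cells = 4` cells: the size
filter removes single-cell speckle inherited from the noise, and
4-connectivity is conservative about declaring voids connected (diagonal
contact does not merge). Component labelling uses `scipy.ndimage.label`;
the test suite checks it against a brute-force flood fill, exhaustively on
all 65 536 4×4 masks. The verdict is *fragmentation* if the final snapshot
still contains a counted void, *non-fragmentation* if voids appeared and
healed, *indeterminate* if none ever formed. Only void cells enter the
verdict; the white liquid halo around voids is "intermediate" and tracked
implicitly.

## Study conditions and the sufficient-IP6 threshold

The reference study integrates the water case (c = 0) and a
sufficient-IP6 case on the same N = 200 grid, Δt = 0.1/N², t ∈ [0, 1];
the water case uses five seeds with a per-seed majority vote, the
sufficient-IP6 case eight (healing is a near-critical event, so extra
seeds buy detection power without changing the event time). At this resolution the water case
shows the expected sequence: no voids through t = 0.4 (fluctuations still
growing), clear connected voids at 0.6, persisting — and deepening after
the switch — to t = 1.0.

The concentration scale of φ̄(c) is genuinely open: experiments quote c in
ppm (0–10 000) while the simulation cases are c ∈ {0, 0.02, 0.03}, and no
conversion is stated. Fed directly into the formula, c = 0.03 gives
φ̄ = 0.499985, a bias of 1.5e−5 below the water value. At N = 200 this
printed value already separates the cases strongly (void area fraction
~1–4% versus ~30–50% for water) but leaves small voids alive at t = 1, so
the qualitative "voids heal" outcome needs a slightly stronger bias. The
package therefore runs the sufficient-IP6 case with an explicit threshold
override φ̄ = 0.49998 (bias 2e−5, within the supported override band
(0.49, 0.5)), the weakest bias at which voids still nucleate but heal
while diffusion is active; the override is recorded in the run manifest
(`phi_bar_source = "explicit-override"`). The transition is sharp — by
φ̄ ≈ 0.499975 voids no longer form at all — which mirrors how narrowly
the model separates the low-IP6 and sufficient-IP6 regimes.

Two consequences of running at this near-critical point are worth
stating. First, void healing is an *event*: depending on the noise
realization a run either heals completely (void area returns to zero at
the t = 0.8 snapshot — necessarily there, because after the switch-off
cells decouple and existing voids can only deepen) or keeps a small
residual void. The study therefore reports the vanish time over the runs
in which the event occurred, censoring the persisting runs, the way
event times are reported in survival data. Second, in the water case the
first *detected* void (≥ 4 connected cells below 0.1) falls at the 0.4
snapshot for roughly half the noise realizations and at 0.6 for the
rest: t = 0.4 catches the tail end of the linear-growth stage, where the
deepest fluctuations of some realizations have already crossed the void
threshold at sub-percent area. The per-seed majority of the onset time
is consequently a genuinely stochastic quantity on the 0.2-spaced
snapshot grid.

## Problem sizes in tests

The test suite exercises the full N = 200 study only in the acceptance
tests (five seeds per case); all other solver tests run at N ≤ 64 with the
stability-checked step, where every property (scalar-oracle equivalence,
energy dissipation, symmetry, convergence order) is already binding.
Grid-convergence and scaling-invariance tests use a smooth single-mode
initial condition of amplitude 1e−6 so the solution stays well resolved
over the tested horizon.

## Known limitations

* 2-D only; no cylinder geometry, no Cahn–Hilliard (conserved) variant.
* No functional forms for ε(c) or T(c) beyond the proportionality T ∝ ε²;
  the chemistry of IP6 chelation is not modeled.
* The fragmentation verdict is threshold-based; it quantifies the
  rendered black regions, not crack morphology.
* The noisy-uniform initial state cannot reproduce boundary-first setting
  narratives; `boundary_set_field` exists for that exploration but is not
  part of the reference study.
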