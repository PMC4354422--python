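# Model and numerical methods

## The model

`chondrosim` simulates the inflammatory response of articular cartilage
(superficial zone) in the two weeks after a single blunt impact, on a
circularly symmetric explant of radius 2.5 cm with an impact region of
radius 0.25 cm. Chondrocytes are immobile; chemicals diffuse. The state
comprises

* **cell compartments** (cells/cm²): healthy unsignaled `C_U`; healthy
  ROS-signaled pre-catabolic `C_T(a)`, structured by time-since-signaling
  `a`; EPO-producing healthy `C_E`; catabolic `S_T(a)` (age-structured);
  EPOR-active `S_A`; necrotic `D_N`. Apoptotic and cleared-necrotic cells
  leave the live system; they are tracked in explicit accumulators so the
  local cell budget closes exactly.
* **chemicals** (nanomolar): reactive oxygen species `R`, alarmins
  (DAMPs) `M`, the pro-inflammatory cytokine IL-6 `F`, and the
  anti-inflammatory cytokine erythropoietin (EPO) `P`. All four diffuse
  radially, `(1/r)∂_r(r D ∂_r u)`, with zero-flux conditions at the
  center and at the outer edge (closed explant — the outer condition is a
  modeling choice; only the center condition is dictated by symmetry).
* **extracellular matrix** `U` (dimensionless density, initial value 30),
  degraded by IL-6 with saturation and gated off entirely once EPO
  exceeds the threshold `P_c`.

Transitions between compartments are driven by saturating (Hill-type)
responses `x/(λ+x)` and, for the two delayed transitions
(`C_T → C_E` at age `τ₂ = 1` d, `S_T → S_A` at age `τ₁ = 0.5` d), by a
smoothed transition-age kernel

    γ(a − a_max) = (γ₀/σ) · [tanh((a − a_max)/σ) + 1],

which concentrates the transition near `a_max` and sharpens as `σ → 0`.
The kernel height `γ₀ = 1` and spread `σ = 0.05` d are package defaults
(the kernel's shape parameters have no published values); both are
configurable. With `σ = 0.05` d the transition window is ≈0.1 d wide,
sharp on the day scale of `τ₁, τ₂` while still resolved by the default
age grid (see below). Age structure replaces discrete delay terms: a cell
signed into `C_T` or `S_T` enters at age 0, ages at unit rate, and its
delayed transition fires when its age reaches the transition age.

Two Heaviside gates encode the anti-inflammatory switch: ECM degradation
and the DAMPs/IL-6 catabolic signaling run only while `P < P_c`, and the
reversion `C_E → C_U` (rate `α₂`) only once `P > P_c`. `H(0) = 0` by
convention; the baseline trajectory never touches the threshold, so the
convention is inert. Under the baseline parameterisation EPO never
reaches `P_c = 1` nM (it peaks near 0.04 nM), so all gates are constant
for the entire run — the simulator reports the running max of `P` and a
gate-fired flag as diagnostics.

One printed form required a correction for consistency: the `S_T`
age-boundary inflow is implemented as
`(β₁₁·M/(λ_M+M) + β₁₂·F/(λ_F+F))·H(P_c−P)·∫C_T da`, i.e. exactly the
DAMPs/IL-6 sinks integrated over the `C_T` age distribution, so cell
number is conserved across the transition. The rate scale of the delayed
`S_T → S_A` transition is `κ₁` (value 10/day), pairing it one-to-one
with `κ₂` for `C_T → C_E`. `σ_U` is carried as a loadable parameter but
appears in no rate. `P_c` is a concentration threshold (nanomolar).

## Discretization

**Space.** Uniform cell-centered finite-volume grid on `[0, r_max]`
(default 200 intervals); unknowns live at annulus centers, fluxes at
edges. This keeps the scheme second order for smooth fields, avoids the
`1/r` singularity, conserves area-weighted mass to round-off, and makes
the zero-flux conditions exact. Cells whose center lies inside the
impact radius start necrotic; with the default grids the impact edge
coincides with a cell edge.

**Age.** Uniform finite-volume bins on `[0, a_cap]` (default 129 bins,
`a_cap = 3` d), unknowns at bin centers, first-order upwind transport at
unit speed in flux form. The bin form is what makes the cell bookkeeping
exact: over one step the discrete age mass changes by
`dt·(inflow − last-bin density)` identically, so the boundary inflow
pairs exactly with the source-compartment sink and the outflow past
`a_cap` accumulates in a nonnegative `aged_out` field. Age integrals use
the midpoint rule (exact for integrands linear in age, second-order
otherwise). `a_cap = 3` d is three times the largest transition age; the
kernels drain the age compartments shortly after `τ₁, τ₂`, so the
density reaching `a_cap` is negligible wherever the driving signals are
present (the residual last-bin density is reported as a diagnostic).

**Time.** IMEX splitting in a fixed order (reactions → aging →
diffusion), so runs are bit-reproducible:

1. all reaction and transition terms advance explicitly (forward Euler);
2. the age densities advect by upwind transport with their boundary
   inflows;
3. each chemical solves `(1 + dt·δ)I − dt·L` implicitly (backward
   Euler), a tridiagonal M-matrix system per species — stiff decay
   (`δ_R = 60`/day) and diffusion are unconditionally stable and
   positivity-preserving. The ECM updates explicitly (it neither
   diffuses nor is stiff).

The step size is adaptive by step doubling: one step of `dt` is compared
against two steps of `dt/2` in a per-field relative max-norm; the
half-step solution is accepted when the estimate is below `tol`
(default 1e-5), otherwise `dt` halves and retries; after acceptance the
step may grow by at most a factor 2. Each field's error is scaled by its
own max with a floor at 10⁻³ of its characteristic magnitude (derived
from the parameters: e.g. `σ_R·n₀` for ROS) — a pure relative norm
stalls at `t = 0` on fields that are just being born, whose own
magnitude is `O(dt)`. `dt` is additionally capped at the age spacing
(upwind CFL) and clipped to land exactly on snapshot times. The full
14-day baseline takes ≈3·10⁴ accepted steps at the default tolerance.

Negative values can only arise in near-empty age bins under the explicit
sink update; accepted states are clipped at zero and entries below
−10⁻⁶ are counted and reported (the baseline run has zero such clips).

## Conservation

For every radius,
`C_U + ∫C_T + C_E + ∫S_T + S_A + D_N + D_A + N_cleared + aged_out`
equals the initial 100,000 cells/cm² to round-off at every accepted
step: each transition's sink and source use the same discrete quadrature
and gates, apoptosis and necrotic clearance accumulate explicitly, and
the age advection is exactly mass-accounting. This is asserted per
snapshot and is the primary structural self-check of the implementation.

## Verification

* **Oracle equivalence.** An independent method-of-lines reference (the
  same semi-discrete system written from scratch in the test suite,
  integrated with a high-accuracy stiff BDF solver) agrees with the IMEX
  integrator within 0.5% relative max-norm per field on a 20×16 grid
  over 2 days.
* **Grid convergence.** Refining the radial grid (100 → 200 → 400
  intervals, reference 1600 = 16× the coarsest) drives every variable's
  day-14 relative max-norm error down at clean second order (measured
  factors ≈4 per doubling). "Relative error" here means: reference
  linearly interpolated to the coarse centers, max-norm difference at
  day 14 divided by the reference's max-norm. Under this conservative
  pointwise measure the worst variable sits at ≈1.4% on 100 intervals
  and drops below 0.3% by ≈400 intervals: the error constant is set by
  the ROS diffusion–decay boundary layer of width
  `sqrt(D_R/δ_R) ≈ 0.04 cm`, under-resolved at `dr = 0.025 cm`.
  Integral norms, or a different discretization, give much smaller
  numbers: convergence-error tables are scheme- and norm-specific and
  are not comparable entry for entry across implementations.
* **Closed forms.** The decoupled necrotic pool decays as
  `10⁵·e^(−μ_DN t)`; isolated chemicals follow the backward-Euler decay
  factor exactly; the ECM is constant when IL-6 is absent or EPO exceeds
  threshold; a Neumann disk Bessel mode reproduces its analytic decay
  rate at second order in `dr`.

## Sensitivity study

One-at-a-time perturbations around the baseline (13 parameters × 4
values by default, at reduced spatial resolution `n_r = 100`). Each
tracked output is summarized by its area-weighted spatial integral at
day 14; directions of change are evaluated across the values inside each
parameter's qualitative-stability interval with a 1% "appreciable
change" threshold. Trajectories are classified monotone vs oscillatory
from the per-step spatial-integral series (≥2 significant
direction reversals after a 2-day transient), which operationalizes
"qualitative change". Notes:

* `α₂` multiplies a gate that never opens in the baseline, so perturbing
  it reproduces the baseline bit for bit.
* `Λ` (IL-6 suppression of EPO production) enters as `Λ/(Λ+F)` with
  `F ≪ Λ`, so perturbing it changes EPO production by well under 1% —
  "no appreciable effect", but not bitwise identity.
* The `β₁₁` row of the default perturbation plan (values {50,75,125,150},
  interval [60,70]) is internally inconsistent — the interval contains
  none of the values and excludes the base value 100; it is reproduced
  as printed and excluded from automated direction checks.

## Known limitations and choices

* The healthy density `C_U` is *almost* nonincreasing in time: late in
  the run the EPO-driven recovery `α₁·S_A·P/(λ_P+P)` can exceed the weak
  re-signaling sink at mid radii and lift `C_U` by <1% of the initial
  density over days. The qualitative test asserts monotone decline with
  a 1% tolerance, below what radial profile plots resolve.
* Single impact only; no cyclic loading, no EPO-therapy scenario runs
  (the `P ≥ P_c` gates are implemented, so such runs only need a
  parameter change), no spatial heterogeneity of the impact, no
  mechanical-stress coupling.
* First-order upwind in age introduces numerical age diffusion at
  CFL < 1; fidelity is enforced behaviorally through the oracle and
  convergence tests rather than by replicating a characteristics-aligned
  age-stepping scheme.
* The adaptive tolerance, step bounds and `a_cap` have no published
  values; the defaults above are package choices, exposed in
  `NumericsConfig`.
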