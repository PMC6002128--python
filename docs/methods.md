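# Methods

`stripesim` models colonies of engineered *E. coli* in which the
chemotaxis pathway is wired to a quorum-sensing module through CheZ.
This note records the models, the numerical schemes, and the design
choices made where more than one reasonable option existed.

## Single-cell layer

### Signaling

Each cell carries two slow internal variables: total CheZ `z` (μM) and
the mean receptor methylation level `m` (dimensionless).

* CheZ: `dz/dt = kV(Zw − z)` while local AHL `h < h0`, and `dz/dt =
  −kV·z` once `h ≥ h0` (quorum suppression of *cheZ*; the boundary
  `h = h0` is assigned to the suppressed branch).  `kV = r·n` ties CheZ
  turnover to growth: without production, dilution by growth is the only
  sink.  An optional logistic blend of the two branches is provided for
  numerical experiments but is off by default — the biological switch is
  ultrasensitive, and simulations with a soft switch lose the sharp
  stripe boundaries.
* Methylation: `dm/dt = kR·R(m)(1−A) − kBp·Bp·A`, with receptor
  activity `A(m) = 1/(1+exp[Nr·α0(m0−m)])` and free CheR reduced by
  sequestration on inactive receptors, `R = Rt/(1+KR·Tt(1−A))`.
* The fast phospho-proteins (receptor-CheA `Tp`, CheY-P `Yp`, CheB-P
  `Bp`) are in quasi-steady state.  Their three balance equations plus
  conservation laws reduce, for given `Yp`, to closed forms for free
  CheZ, `Tp`, free CheB and `Bp`; the remaining scalar CheA balance is
  solved for `Yp` by bracketed Brent iteration on `[0, Yt]`.  Past the
  pole of the inner `Tp` expression the residual is clamped to a large
  negative constant, which keeps the bracket on the unique nonnegative
  physical root; accepted solutions must satisfy all residuals to
  `1e-10·kA·Tt`.  Newton-type iteration is deliberately avoided: the
  system is ultrasensitive near the activity transition and an
  unbracketed iteration can diverge or land on a nonphysical root.
* `m*(z)` (the quasi-steady methylation) is found by bracketed root
  search of `dm/dt` on `m ∈ [0, 3]`, widened once on failure.

The CheR⁻CheB⁻ double knockout is modeled by removing the CheB branch
(`Bt = Bp = 0`) and freezing `m` at a user-supplied value (default
0.707, near the baseline quasi-steady level): with no
methylation/demethylation enzymes the receptor state cannot adapt.

### Motility

A cell has `nf = 8` flagellar motors switching independently between CCW
and CW at CheYp-dependent rates `λf = a1·exp(b1·Yp)` and
`μf = a2·exp(−(b2−Yp)⁴/c)`; it runs when at least `w = 6` motors are
CCW.  With the binomial occupancy `P_i`, whole-cell rates follow from a
voting argument: `λ = w·λf·P_w/P_run` (a run ends when one of exactly
`w` CCW motors flips) and `μ = (nf−w+1)·μf·P_{w−1}/P_tumble`.  Since
`b2 < 0`, `μf` needs no clamping for physical `Yp ≥ 0`.

The effective diffusivity of the run-and-tumble walk in `d` dimensions
is `D(z) = s0²·μ0/(d·λ0·(μ0+λ0))` with both rates evaluated at
`m*(z)`.  At the wild-type CheZ level cells run ~90% of the time and
`D ≈ 6.2×10⁻⁴ mm²/s`; at `z = 1.11 μM` the run fraction collapses to
~27% — the ultrasensitivity that makes density-suppressed motility work.

All solver loops read `m*(z)`, `Yp*(z)`, `λ0`, `μ0`, `D` from tables on
a uniform z-grid (spacing 0.005 μM, linear interpolation) and, for the
agent model, `Yp(m, z)` and `dm/dt(m, z)` from a uniform (m, z) grid
(0.01 × 0.005).  All tabulated curves are smooth on those spacings, and
rebuilding costs a few seconds of root solves per parameter set, so the
tables are cached per parameter bundle.

## Agent-based (hybrid) colony model

Cells are particles on `[−L, L]` (1D) with position, ±1 heading, a
run/tumble flag and internal state `(z, m)`.  AHL and nutrient live on a
uniform node grid (spacing 0.1 mm) with no-flux boundaries.

Operator splitting per field step (1 s):

1. **Internal state + rates**, every `dt_internal = 0.2 s`: explicit
   Euler for `z` (timescale ~1/r ≈ 43 min, so 0.2 s steps are far inside
   stability), explicit Euler for `m` with a monotonicity clamp — if a
   step would cross `m*(z)` it lands exactly on it.  The clamp
   stabilizes the mildly stiff methylation dynamics near the activity
   transition without a nonlinear solve; it can only shorten the
   distance to equilibrium, which is also the direction of the exact
   flow.  Cells sitting exactly at the unsuppressed fixed point
   `(Zw, m*(Zw))` take a cached fast path.
2. **Motion**: the velocity-jump process is simulated *exactly* within
   each rate-refresh interval — exponential run/tumble waiting times are
   sampled event by event, runs displace at `s0`, walls reflect, and a
   tumble→run transition draws a fresh uniform heading.  An earlier
   per-step Bernoulli discretization was measured to bias the realized
   diffusivity by −4% at a 0.05 s step; the event-driven scheme is
   unbiased for any refresh interval and cheaper (a tumbling cell
   averages about one event per interval).
3. **Division**, per field step: each cell divides with probability
   `1 − exp(−r·n(x)·dt)` — exact for a Poisson process at any `dt`.  The
   daughter sits at the mother's position, inherits `(z, m)` and the
   movement state, and gets a fresh heading.  Inheritance of the
   internal state preserves the population structure over `z` that the
   mean-field model evolves.
4. **Fields**: implicit (unconditionally stable) diffusion via a
   tridiagonal solve; decay and consumption applied as exact exponential
   factors; each cell deposits `αd/dx` on its nearest node.  With no
   cells, a uniform AHL field decays as `exp(−βt)` to machine precision.

Cells read `h` and `n` by linear interpolation at their position.
Per-realization RNG: one numba generator (motion events) and one NumPy
generator (initialization, division), both seeded from
`seed + 9973·realization`, so snapshot streams are bit-reproducible.

The 2D agent model is exercised through the frozen-state velocity-jump
walker (uniform headings on the circle/sphere) used for the
mean-squared-displacement validation; the fully coupled colony loop is
1D, which covers every scenario the agent model is compared on — the
radial plate predictions come from the mean-field model.

### What the agent model emulates — and what it does not

It generates the study conditions themselves: 500 cells inoculated as a
Gaussian (σ = 2 mm) at the domain center with equilibrium internal
state, nutrient at 1, no AHL.  A cheaper variance-only rescaling
(`agent_scale = a`) divides the cell count and density scale by `a` and
multiplies the per-cell rates `αd, γd` by `a`: the mean-field limit is
unchanged while sampling noise grows by `√a`.  The model does not
include mechanical cell-cell interactions, nutrient-dependent speed,
directional persistence after tumbles, cell-cycle-resolved division or
signaling noise; agreement between the two model tiers therefore
validates the mean-field closure, not those biological refinements.

## Mean-field model

The state is `ρᶻ(x, z, t)`, the cell density over space and internal
CheZ, coupled to `h` and `n`:

```
∂t ρᶻ = ∇·(D(z) ∇ρᶻ) − κ ∂z(g(z,h) ρᶻ) + r n ρᶻ
∂t h  = Dh Δh + α ρ − β h,      ∂t n = Dn Δn − γ ρ n,    ρ = ∫ρᶻ dz
```

with `α = αd·ρs`, `γ = γd·ρs`, `ρs = 1000 cells/mm`, and `κ` a
dimensionless multiplier on the CheZ turnover (κ = 1 is the baseline).
Methylation does not appear: it is slaved to `m*(z)` inside `D(z)`,
justified by its fast timescale relative to CheZ turnover.

Discretization (finite volumes, cell-centered):

* Geometry enters only through face areas and cell volumes; in radial
  symmetry the inner face has zero area, which is the standard
  regularization of the coordinate singularity (a uniform profile stays
  uniform to machine precision), and the outer wall face is zeroed for
  no-flux.
* **Spatial diffusion**: implicit per z-level with prefactorized Thomas
  solves (the matrix depends only on `D(z)·dt`).  Conservative by
  construction.
* **z-advection**: explicit, conservative, first-order upwind with the
  velocity `κ·g` evaluated at z-faces and zero flux at `z = 0` and
  `z = Zmax = 1.05·Zw`.  `g` switches sign with `h`, and the switch is
  sharp, so a monotone scheme is required; higher-order non-monotone
  schemes oscillate at the branch boundary.  The time step is capped by
  the advection CFL `0.8·dz/(κ·r·n0·Zmax)` (≈ 35 s at κ = 1; the 2 s
  default is far below it).
* **Growth and field reactions**: exact exponential factors per step.
* Initial data: the z-delta at `Zw` is realized as all mass in one
  z-cell, cell-averaged so the spatial marginal is grid-exact.  The
  z-grid is offset (by at most half a cell) so that this cell's center
  coincides with `Zw` exactly: `D(z)` is steep near `Zw`, and without
  the offset the initial cohort would carry a diffusivity evaluated up
  to half a cell away — a 15% coefficient error at Nz = 60.  With the
  aligned grid the colony-scale observables are z-grid-converged already
  at Nz = 60 (total mass changes < 0.1% from Nz = 60 to 240).

With growth off, transport conserves mass to 1e-10 over 10⁴ steps in
both geometries, and densities remain nonnegative (upwind + implicit
diffusion + positive growth factors).


The **reduced model** replaces the internal variable by its steady
state: `∂tρ = Δ(D̄(h)ρ) + r n ρ` with `D̄ = D(Zw)` below threshold and
`D(0)` above (note the flux is `∇(D̄ρ)`, not `D̄∇ρ`).  It is solved
implicitly with the switch evaluated at the current AHL field.  During
stripe formation CheZ is in fact broadly distributed (its turnover is as
slow as growth), so the reduced model is shipped as a comparison object,
not as an approximation we rely on.

## Pattern metrics

On a density profile `ρ(ξ)` at fixed time:

* **Front position**: outermost crossing of a threshold (default 0.1 in
  ρs-normalized units), linearly interpolated; **front speed**: least
  squares slope of the front position over 10–20 h, in mm/h.
* **Stripes**: interior local maxima with prominence ≥ 10% of the
  profile maximum, excluding the outermost (front) peak.  Prominence
  threshold and front exclusion are operational choices; they are
  applied uniformly across all runs and sweeps.
* **Wavelength**: mean separation of successive stripe peaks.
* **Height ratio** `h2/h1`: per stripe, `h1` is the peak density and
  `h2` the *global* minimum between this peak and the next one (sharp
  stripes at fast CheZ turnover develop secondary shoulders; nearest
  local minima would land on a shoulder and overstate `h2`).  The
  central dome is treated as a peak so the innermost stripe has a left
  neighbor.
* **Density ratio**: the coordinate-weighted mean density over one full
  wavelength (between the bracketing minima), divided by `h1`:
  `∫ξρ dξ / (h1 ∫ξ dξ)`, with the `ξ` weight dropped in Cartesian
  geometry.  This normalization (stated in every metrics report header)
  makes the flat-profile limit equal 1 and the thin-annulus square-wave
  limit equal the stripe's area fraction.
* **Stripe formation times**: the first snapshot at which the interior
  peak count reaches a new maximum, one time per stripe; intervals are
  averaged for the formation-interval statistic.

## Problem sizes and baseline scenarios

* Radial plate baseline: R = 50 mm, Nx = 500 (0.1 mm), Nz = 60,
  dt = 2 s, 12.5 h; runs in ~15 s.  The front stays > 20 mm from the
  wall; a runtime check fails the run otherwise.
* 1D cross-validation: [−25, 25] mm, T = 5 h, six agent realizations
  versus the mean-field run on identical 0.1 mm bins (Nz = 240); the
  relative L¹ distance of the final density is the headline statistic.
* Sweeps (speed 0.016–0.032 mm/s, doubling time 24–36 min,
  κ ∈ {0.6, 1, 3, 10}) use 0.2 mm grids, dt = 4 s and domains sized so
  the front never reaches the wall (up to R = 90 mm for the fastest
  cells); each run reports front speed, wavelength and stripe-structure
  ratios at 20 h.  Sweep ranges are set so that discrete stripes exist
  across the range: well below s0 ≈ 0.014 mm/s (or above ~38 min
  doubling time) AHL stays above threshold everywhere behind the front
  and the interior becomes a single trapped zone with no periodic
  structure.

## Known limitations

* First-order upwind in `z` is diffusive; Nz = 60 suffices for pattern
  metrics but quantitative z-distributions need Nz ≳ 200.
* The agent model's colony front is a discrete pulled front and lags
  the mean-field front by the classic particle-number cutoff (the
  correction scales with 1/ln²N, so it is nearly insensitive to
  doubling the cell count).  In a front-free setting (uniform density)
  agent and mean-field growth agree to 0.1%; in colony runs the lagging
  front removes a few percent of total mass (the front is where
  nutrient is fresh) and advances quorum-threshold crossing slightly
  inward, so the first stripe nucleates at a smaller radius than in the
  mean field.  This is intrinsic to comparing particles with their
  mean-field limit at realistic cell numbers and is the dominant term
  in the cross-model L¹ discrepancy at early times.
* Late-time front dynamics depend on the global nutrient reservoir
  (domain size): fronts decelerate once the whole dish is depleted.
  Comparisons fix the domain, and sweep domains are chosen large enough
  that the 10–20 h window is reservoir-limited as little as possible.
* The basal-state turning rates are exquisitely sensitive to the
  quasi-steady methylation root (a 5×10⁻⁵ shift in `m*` moves λ by
  ~1%); reference values computed with looser root tolerances differ
  from this package's converged values by about that much.
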