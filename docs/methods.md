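# Methods

## Model

The package implements a two-species stoichiometric predator–prey system
for tumour (prey, carbon biomass `x`) and cytotoxic immune cells
(predator, carbon biomass `y`) in a closed potassium environment. The
modelling assumptions are:

- all biomass is measured in carbon; every other nutrient except
  potassium is assumed abundant;
- the total potassium mass `K_t` is fixed (closed system) and splits
  into three pools, tumour (`Q·x`), immune (`θ·y`) and free (`K_f`),
  with `K_f = K_t − Q·x − θ·y` by construction;
- immune stoichiometry is rigid (constant quota `θ`); tumour
  stoichiometry is flexible: the quota `Q` varies but never falls below
  a minimum `q`;
- tumour growth obeys the Droop law `μ_m(1 − q/Q)` under potassium
  limitation and a logistic law with carrying capacity `L` under carbon
  limitation, combined by Liebig's minimum principle on the per-capita
  rates;
- immune recruitment is proportional to predation, `e·f(x)·y`, at full
  efficiency while the prey is potassium-rich (`Q ≥ θ`) and reduced to
  `e·(Q/θ)·f(x)·y` when prey is potassium-poor — eating low-quality prey
  yields fewer predators;
- two non-stoichiometric interaction terms: coercion `−l·x·y` (immune
  cells recruited by the tumour into a tumour-promoting role) and a
  constant influx `u` (treatment surrogate), giving the tumour-free
  equilibrium `(0, u/d)`.

### Quota closure

The quota ODE `dQ/dt = α·K_f − μ_m(1 − q/Q)·Q` operates on the fast
metabolic time scale, so `Q` is eliminated by a quasi-steady-state
closure. Two closures are provided and switchable everywhere:

- `qss` (default): `Q = (q·μ_m/α + K_t − θ·y)/(μ_m/α + x)`, which
  retains the uptake constant `α` and the true maximal growth rate
  `μ_m`. Under this closure the free pool reduces to
  `K_f = (μ_m/α)(K_t − θy − qx)/(μ_m/α + x)`, so `K_f ≥ 0` is exactly
  the trapezoid constraint `s·x + y ≤ p` in scaled coordinates.
- `lke`: the `α → ∞` limit `Q = (K_t − θ·y)/x`, in which all free
  potassium is instantaneously absorbed by the tumour (`K_f ≡ 0`). At
  `x = 0` the quota is taken as `+∞` (its limit), which saturates the
  `min(·, Q/θ)` branches and keeps the vector field continuous on the
  y-axis.

Both closures give the same zero set for the potassium-limited growth
branch (`x = (K_t − θy)/q`) and the same boundary point
`k = min(L, K_t/q)`, so the invariant-region geometry is
closure-independent.

### Growth law form

The tumour equation uses the minimum of per-capita rates,
`b·x·min(1 − x/L, 1 − q/Q)`. Under the `lke` closure this is
algebraically identical to a logistic law whose carrying capacity is the
minimum of the carbon ceiling and the potassium ceiling; under `qss` the
two readings differ in shape but share the same zero set. The
min-of-rates form is taken as canonical because it is the direct
expression of Liebig's principle.

### Scaled form

`scale()` maps `(K_t, q, θ) → (p, s) = (K_t/θ, q/θ)`; `p` is the
maximal immune density the potassium pool can support and `s` the quota
ratio. The map is a bijection up to the θ-gauge: rebuilding with any
`θ' > 0` yields an identical vector field (tested to machine precision).

## Discrete analogue

The map freezes both per-capita rates at the start of each unit interval
and integrates exactly, giving `x' = x·e^{g_x}`, `y' = y·e^{g_y}` with
`g_x = b·min(1 − x/L, 1 − q/Q) − P(x)·y`, `g_y = e·min(1, Q/θ)·f(x) −
l·x − d + u/y` and `P(x) = f(x)/x` (extended by `f'(0)` at `x = 0`). The
treatment influx is frozen per capita (`u/y` inside the exponent); an
alternative variant that freezes only the linear per-capita part and
integrates the constant influx exactly (`y' = y·e^g + u(e^g − 1)/g`) is
available behind a flag. Both variants share every fixed point with the
ODE because the exponents vanish exactly where the per-capita rates do.
Exponents are capped at ±50 with a diagnostic counter rather than
overflowing: chaotic sweeps can transiently produce enormous rates.

## Numerical choices

- **Integration**: `scipy.integrate.solve_ivp`, LSODA, `rtol 1e-8`,
  `atol 1e-10`. The vector field is continuous with kinks on two switch
  surfaces (carbon↔potassium limitation, quota-rich↔poor recruitment);
  no event location is needed, and crossings are detected post hoc from
  branch labels. Components more negative than `−atol` never occur in
  the invariant region; tiny negatives are clipped and counted.
- **Jacobians**: analytic piecewise partials (one-sided on switch
  surfaces, flagged). Cross-validated against central differences with
  coordinate-scaled steps — the `u/y` term makes the map's curvature
  grow like `1/y²`, so a fixed step would swamp the comparison with
  truncation error.
- **Equilibria**: a 50×50 grid of seeds over the trapezoid (configurable;
  tests use coarser grids) feeding `scipy.optimize.root` (hybr), root
  deduplication radius `1e-6`, acceptance residuals `1e-10` (ODE) and
  `1e-8` (map fixed point). An empty interior set is a valid outcome.
- **Stability**: ODE verdicts from eigenvalue real parts (saddle iff
  `det < 0`); map verdicts from the Jury inequalities
  `|tr M| < 1 + det M < 2`, always cross-checkable against spectral
  radius. Non-hyperbolic cases (within `1e-9` of the boundary) are
  reported as such, never misclassified. Nullcline slopes `−F_x/F_y`,
  `−G_x/G_y` and the potassium-region label (`Ω1: Q ≥ θ`, `Ω2: Q < θ`)
  are reported with flags for the slope-comparison theorem clauses; the
  verdict always comes from the eigenvalues.
- **Invariant region**: forward invariance is audited numerically — the
  inward normal component of the field on sampled boundary points
  (bottom edge flux is `u ≥ 0`; the y-axis is itself invariant) plus a
  free-potassium sign audit on interior samples. The closed-form bound
  on the admissible influx `u` is not derived; the audit exposes the
  empirical margin instead, and a large enough `u` is correctly reported
  as violating the potassium-ceiling edge.
- **Phase classification**: elimination requires a stable tumour-free
  equilibrium and tumour biomass below `1e-6` sustained over the last
  10% of the horizon; sustained oscillation requires amplitude `> 1e-4`
  that is *not* decaying window-over-window (a slowly converging focus
  shrinks by more than 30% per window and is classified as convergence).
  Default horizon 800 days from three spread starts inside the
  trapezoid.
- **Sweeps**: warm-started by default (final state carried to the next
  parameter value), cold-start available. Discrete protocol: 2000
  burn-in iterates, 300 samples; continuous: 500-day transient, 200-day
  recording window at 0.1-day spacing. Period detection is by
  near-recurrence (`< 1e-4` in max norm) up to period 64; the continuous
  model reports period 1 for point attractors and 0 otherwise. The
  maximal Lyapunov exponent propagates a tangent vector through the
  analytic map Jacobian with per-step renormalization.

## Reference parameters

The shipped reference set (`K_t 0.025`, `e 0.8`, `b 1.2/day`,
`d 0.25/day`, `θ 0.03`, `q 0.0038`, `c 0.81/day`, `a 0.25`,
`μ_m 1.2/day`, `α 10/day`, `L ∈ 0.25–2.0`) mimics laboratory
stoichiometric grazer experiments rather than any clinical measurement;
its value is qualitative (it produces the sign structure that makes the
stability analysis interesting). The carrying capacity is a range and
must be chosen per experiment. The coercion rate `l` and influx `u`
default to 0 (the plain stoichiometric predator–prey reduction) and are
set per scenario: the carrying-capacity sweep family uses `l 0.2`,
`u 0.05` with `K_t ∈ {0.045, 0.06}`; the growth-rate sweep family uses
`l 0.009`, `u 0.02`, `L 1.6`. The growth-rate sweep range `b ∈
[0.8, 3.5]` brackets the continuous-stable and chaotic regimes and is
configurable. The tumour death rate is treated as absorbed into the net
growth rate `b`; `μ_m` appears only inside the quota closure.

## What the experiments show, and what they do not

All experiments are self-contained simulations; there is no external
data and no fitting. Passing tests establish internal mathematical
consistency (shared equilibria, correct linearizations, invariance,
limit reductions) and the qualitative dynamical claims (protective
direction of total potassium, three immunoediting phases, period
doubling to chaos in the map) *for this model at these parameters*. They
say nothing about clinical potassium dynamics: the parameter set is
borrowed from plankton stoichiometry, the "treatment" is a constant
influx, and the chaotic regime of the map is a property of the
discretization, not an observed phenomenon. The immune minimum at the
top of the carrying-capacity range depends on which attractor the fixed
initial condition `(0.3, 0.3)` selects — the system is bistable there —
so the direction-of-effect comparisons use cold starts at that common
initial state.

## Testing strategy

Unit tests freeze hand-derived closed-form values (quota, growth factor,
boundary linearization `−d` / `1 − d`, Monod half-saturation);
independent-oracle tests compare the full model's `l = u = 0` reduction
against a separately coded transcription of the reduced equations, the
map against a brute-force arithmetic oracle, period detection and
Lyapunov exponents against the quadratic test map (exponent `ln 2` at
growth 4); property tests cover the θ-gauge, Jury/spectral-radius
equivalence, pool conservation, and the free-pool/trapezoid sign
identity. The refinement-consistency test composes the frozen-rate map
over substeps `1/m` and checks convergence to the time-1 ODE flow;
monotone error decay is asserted from `m = 2` on because the single
coarse step can fortuitously cancel. Problem sizes in the shipped suite
(12–28 sweep values, 30–50 trajectories, 10³–10⁴ random states) are
chosen to keep the full run near a quarter minute while exercising every
code path; all protocols accept larger sizes.
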