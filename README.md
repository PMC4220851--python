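# kstoich

Stoichiometric (potassium-limited) tumour–immune dynamics: a continuous
predator–prey ODE model with Droop cell-quota growth, its discrete
exponential-map analogue, and the dynamical-analysis toolkit around them
— equilibria, Jacobian/Jury stability, invariant-region auditing,
immunoediting-phase classification, and bifurcation sweeps with period
detection and Lyapunov exponents.

## The model

Tumour cells (biomass `x`, the prey) and cytotoxic immune cells
(biomass `y`, the predator) share a closed potassium pool of total mass
`K_t`. Immune cells hold a fixed potassium:carbon quota `θ`; the tumour
quota `Q` varies with a floor `q` and is eliminated by a
quasi-steady-state closure,

```
Q(x, y) = (q·μ_m/α + K_t − θ·y) / (μ_m/α + x)          ("qss")
Q(x, y) = (K_t − θ·y) / x                               ("lke", the α → ∞ limit)
```

Tumour growth follows Liebig's minimum of a carbon-limited logistic rate
and a potassium-limited Droop rate; the immune population is recruited
with an efficiency that degrades when tumour cells are potassium-poor
(`Q < θ`), is coerced by the tumour at rate `l·x`, dies at rate `d`, and
receives a constant therapeutic influx `u`:

```
dx/dt = b·x·min(1 − x/L, 1 − q/Q) − f(x)·y
dy/dt = e·min(1, Q/θ)·f(x)·y − l·x·y − d·y + u
```

with the Monod functional response `f(x) = c·x/(a + x)`. The discrete
analogue freezes the per-capita rates over unit time steps:

```
x' = x·exp( b·min(1 − x/L, 1 − q/Q) − (f(x)/x)·y )
y' = y·exp( e·min(1, Q/θ)·f(x) − l·x − d + u/y )
```

Both models share every equilibrium, including the tumour-free boundary
equilibrium `E₁ = (0, u/d)`. Solutions live in the invariant trapezoid
`{0 < x < k, 0 < y, q·x + θ·y < K_t}`, `k = min(L, K_t/q)` — exactly the
region where the free-potassium pool stays nonnegative. The headline
qualitative results: total potassium plays a protective role (a larger
pool sustains the immune population against larger tumours), the model
realizes all three cancer-immunoediting phases (elimination, equilibrium,
escape), and the discrete map period-doubles into chaos at tumour growth
rates where the ODE settles to a point.

## Worked example

```python
from kstoich import (ModelParams, boundary_equilibrium, classify,
                     classify_phase, find_internal_equilibria)

p = ModelParams(l=0.2, u=0.05, K_t=0.045, L=1.4)   # reference set + treatment

e1 = boundary_equilibrium(p)
rep = classify("continuous", e1, p)
print("E1 =", e1.state, "verdict:", rep.verdict, "eigs:", rep.eigenvalues)

for e in find_internal_equilibria(p, grid_density=15):
    rc = classify("continuous", e, p)
    rd = classify("discrete", e, p)
    print(f"E2 = ({e.x:.6f}, {e.y:.6f})  ODE: {rc.verdict}  "
          f"map: {rd.verdict} (Jury stable: {rd.jury_verdict})  region: {rc.region}")

res = classify_phase(p, t_end=600.0, grid_density=10)
print("phase:", res.phase, "|", res.subcase)
```

prints

```
E1 = (0.0, 0.2) verdict: saddle eigs: [-0.25        0.53813139]
E2 = (0.080421, 0.461394)  ODE: unstable focus  map: unstable focus (Jury stable: False)  region: Omega1
phase: escape | sustained oscillatory coexistence
```

The tumour-free state `(0, u/d) = (0, 0.2)` is a saddle: the immune
direction is stable (eigenvalue `−d = −0.25`) but incipient tumours grow
(eigenvalue 0.538 > 0), so treatment at this rate cannot eliminate the
disease. The single internal coexistence point is an unstable focus for
both models (the Jury test fails for the map), and trajectories settle
into a sustained oscillation of both populations — the escape phase in
the immunoediting taxonomy.

The same toolkit is scriptable from the shell:

```
kstoich equilibria -p u=0.05 -p l=0.2
kstoich sweep --model discrete --param b --start 0.8 --stop 3.5 -p l=0.009 -p u=0.02 -p L=1.6
kstoich scenario run fig2B --out-dir out/
```

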