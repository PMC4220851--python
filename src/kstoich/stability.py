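"""Equilibria, Jacobians, stability classification, invariant-region and
immunoediting-phase analysis.

Writing the continuous model as (dx/dt, dy/dt) = (F, G) and the discrete
map as (x', y') = (R, S), the toolkit locates shared equilibria (the two
models have identical fixed-point sets), builds analytic Jacobians, and
classifies stability: eigenvalue real parts for the ODE, the Jury test
|tr M| < 1 + det M < 2 for the map.  Reports carry the nullcline slopes
-F_x/F_y and -G_x/G_y whose comparison drives the saddle/stable theorem
conditions, the potassium-richness region label (Omega1: Q >= theta;
Omega2: Q < theta), and switch-surface flags.

The invariant region is the open trapezoid (triangle when L >= K_t/q)

    Delta = { 0 < x < k,  0 < y,  q*x + theta*y < K_t },  k = min(L, K_t/q)

equivalently s*x + y < p in theta-scaled coordinates; its interior is
exactly where the free-potassium pool is positive under the qss closure.
Forward invariance is audited numerically by the inward normal component
of the vector field on boundary samples.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
from scipy.optimize import root

from .continuous import (Closure, FeasibilityError, free_potassium,
                         make_response, quota, rates_and_partials, rhs,
                         simulate)
from .discrete import step, step_with_jacobian
from .params import ModelParams, scale
from .response import FunctionalResponse

__all__ = [
    "Equilibrium", "StabilityReport", "InvarianceReport",
    "jury_stable", "boundary_equilibrium", "boundary_equilibria_khe",
    "find_internal_equilibria", "jacobian", "classify", "region_of",
    "invariance_check", "classify_phase", "trapezoid_vertices",
    "e1_scan",
]

ModelKind = Literal["continuous", "discrete"]


# ---------------------------------------------------------------------------
# equilibria

@dataclass
class Equilibrium:
    x: float
    y: float
    kind: Literal["boundary", "internal"]
    rhs_residual: float = math.nan
    map_residual: float = math.nan
    feasible: bool = True

    @property
    def state(self) -> tuple[float, float]:
        return self.x, self.y


def _residuals(x: float, y: float, params: ModelParams, closure: Closure,
               response: FunctionalResponse) -> tuple[float, float]:
    F, G = rhs(x, y, params, closure, response=response, check=False)
    r_c = math.hypot(F, G)
    try:
        xn, yn = step(x, y, params, closure, response=response)
        r_d = math.hypot(xn - x, yn - y)
    except FeasibilityError:
        r_d = math.nan
    return r_c, r_d


def boundary_equilibrium(params: ModelParams, closure: Closure = "qss",
                         response: FunctionalResponse | None = None) -> Equilibrium:
    """The tumour-free equilibrium E1 = (0, u/d).

    With a positive treatment influx it is the model's unique boundary
    equilibrium; with u = 0 it collapses to the origin.  Flagged
    infeasible when the immune standing stock u/d would bind more
    potassium than the pool holds (theta*u/d >= K_t).
    """
    if params.d <= 0:
        raise ValueError("boundary equilibrium needs d > 0")
    resp = response if response is not None else make_response(params)
    y1 = params.u / params.d
    feasible = params.theta * y1 < params.K_t
    r_c, r_d = _residuals(0.0, y1, params, closure, resp) if feasible else (math.nan,) * 2
    return Equilibrium(0.0, y1, "boundary", r_c, r_d, feasible)


def boundary_equilibria_khe(params: ModelParams, closure: Closure = "qss") -> list[Equilibrium]:
    """Boundary equilibria of the l = u = 0 reduction: (0,0) and (k, 0).

    k = min(L, K_t/q) is where tumour growth stalls with no immune cells:
    the carbon ceiling or the point where the quota is drawn down to its
    floor q.  (Identical under both closures.)
    """
    if params.l != 0 or params.u != 0:
        raise ValueError("KHE boundary equilibria require l = 0 and u = 0")
    resp = make_response(params)
    k = min(params.L, params.K_t / params.q)
    out = []
    for x0 in (0.0, k):
        r_c, r_d = _residuals(x0, 0.0, params, closure, resp)
        out.append(Equilibrium(x0, 0.0, "boundary", r_c, r_d, True))
    return out


def trapezoid_vertices(params: ModelParams) -> dict:
    """Geometry of the invariant region Delta in original coordinates."""
    sp = scale(params)
    k = min(params.L, sp.p / sp.s)
    triangle = params.L >= sp.p / sp.s
    return {"k": k, "p": sp.p, "s": sp.s, "triangle": triangle}


def find_internal_equilibria(params: ModelParams, closure: Closure = "qss",
                             grid_density: int = 50, tol: float = 1e-10,
                             dedupe_radius: float = 1e-6,
                             response: FunctionalResponse | None = None
                             ) -> list[Equilibrium]:
    """Locate interior roots of (F, G) inside the invariant trapezoid.

    A grid of seeds over Delta feeds a 2-D Newton-type solve; converged
    roots are deduplicated and kept only if strictly interior, feasible,
    and fixed points of the discrete map as well (shared-equilibria
    contract).  An empty list is a valid outcome.
    """
    resp = response if response is not None else make_response(params)
    geom = trapezoid_vertices(params)
    k, p, s = geom["k"], geom["p"], geom["s"]

    def fun(z):
        x, y = z
        if params.theta * y >= params.K_t or x < 0 or y < 0:
            # steer the solver back toward the feasible region
            return [1e3 * (params.theta * y - params.K_t + 1e-6), 1e3 * max(-x, -y, 0.0)]
        return rhs(x, y, params, closure, response=resp, check=False)

    found: list[Equilibrium] = []
    xs = np.linspace(k / grid_density, k * (1 - 1 / grid_density), grid_density)
    for x0 in xs:
        ymax = p - s * x0
        if ymax <= 0:
            continue
        for y0 in np.linspace(ymax / grid_density, ymax * (1 - 1 / grid_density),
                              grid_density):
            sol = root(fun, [x0, y0], method="hybr", tol=1e-12)
            if not sol.success:
                continue
            x, y = float(sol.x[0]), float(sol.x[1])
            if not (x > dedupe_radius and y > 0 and params.theta * y < params.K_t):
                continue
            if any(math.hypot(x - e.x, y - e.y) < dedupe_radius for e in found):
                continue
            r_c, r_d = _residuals(x, y, params, closure, resp)
            if r_c < tol and (math.isnan(r_d) or r_d < 1e-8):
                found.append(Equilibrium(x, y, "internal", r_c, r_d, True))
    found.sort(key=lambda e: e.x)
    return found


# ---------------------------------------------------------------------------
# Jacobians

def jacobian(model: ModelKind, x: float, y: float, params: ModelParams,
             closure: Closure = "qss",
             response: FunctionalResponse | None = None) -> np.ndarray:
    """Analytic Jacobian of (F, G) or (R, S) at a state.

    On a switch surface the partials are one-sided (active-branch);
    callers needing both sides should perturb across the surface.  At
    x = 0 the continuous Jacobian is lower triangular (F_y = -f(0) = 0).
    """
    resp = response if response is not None else make_response(params)
    if model == "continuous":
        r = rates_and_partials(x, y, params, closure)
        fx, dfx = resp(x), resp.deriv(x)
        F_x = r.mu + x * r.mu_x - dfx * y
        F_y = x * r.mu_y - fx
        G_x = (r.eff_x * fx + r.eff * dfx) * y - params.l * y
        G_y = r.eff_y * fx * y + r.eff * fx - params.l * x - params.d
        return np.array([[F_x, F_y], [G_x, G_y]])
    elif model == "discrete":
        _, J = step_with_jacobian(x, y, params, closure, resp)
        return J
    raise ValueError(f"unknown model {model!r}")


def jury_stable(M: np.ndarray) -> bool:
    """Jury test for a 2x2 matrix: both roots inside the unit circle iff
    |tr M| < 1 + det M < 2."""
    M = np.asarray(M, dtype=float)
    tr = M[0, 0] + M[1, 1]
    det = M[0, 0] * M[1, 1] - M[0, 1] * M[1, 0]
    return abs(tr) < 1.0 + det < 2.0


# ---------------------------------------------------------------------------
# classification

@dataclass
class StabilityReport:
    model: ModelKind
    equilibrium: Equilibrium
    jacobian: np.ndarray
    eigenvalues: np.ndarray
    verdict: str
    trace: float
    determinant: float
    jury_verdict: bool | None
    nullcline_slope_tumour: float
    nullcline_slope_immune: float
    slope_comparison: str          # "immune_smaller" | "immune_greater" | "equal"
    region: str                    # "Omega1" | "Omega2" | "boundary"
    theorem_flags: list[str] = field(default_factory=list)
    on_switch_surface: bool = False

    def to_dict(self) -> dict:
        return {
            "model": self.model,
            "equilibrium": {"x": self.equilibrium.x, "y": self.equilibrium.y,
                            "kind": self.equilibrium.kind},
            "jacobian": self.jacobian.tolist(),
            "eigenvalues": [[z.real, z.imag] for z in np.atleast_1d(self.eigenvalues)],
            "verdict": self.verdict,
            "trace": self.trace, "determinant": self.determinant,
            "jury_verdict": self.jury_verdict,
            "nullcline_slopes": {"tumour": self.nullcline_slope_tumour,
                                 "immune": self.nullcline_slope_immune},
            "slope_comparison": self.slope_comparison,
            "region": self.region,
            "theorem_flags": self.theorem_flags,
            "on_switch_surface": self.on_switch_surface,
        }


_HYPERBOLIC_TOL = 1e-9


def _continuous_verdict(eig: np.ndarray, det: float) -> str:
    re = eig.real
    if det < -_HYPERBOLIC_TOL:
        return "saddle"
    if np.max(np.abs(re)) < _HYPERBOLIC_TOL:
        return "non-hyperbolic"
    complex_pair = np.max(np.abs(eig.imag)) > _HYPERBOLIC_TOL
    if np.all(re < -_HYPERBOLIC_TOL):
        return "stable focus" if complex_pair else "stable node"
    if np.all(re > _HYPERBOLIC_TOL):
        return "unstable focus" if complex_pair else "unstable node"
    if np.any(np.abs(re) < _HYPERBOLIC_TOL):
        return "non-hyperbolic"
    return "saddle"


def _discrete_verdict(eig: np.ndarray) -> str:
    mags = np.abs(eig)
    if np.any(np.abs(mags - 1.0) < _HYPERBOLIC_TOL):
        return "non-hyperbolic"
    complex_pair = np.max(np.abs(eig.imag)) > _HYPERBOLIC_TOL
    if np.all(mags < 1.0):
        return "stable focus" if complex_pair else "stable node"
    if np.all(mags > 1.0):
        return "unstable focus" if complex_pair else "unstable node"
    return "saddle"


def region_of(x: float, y: float, params: ModelParams,
              closure: Closure = "qss", tol: float = 0.0) -> str:
    """Potassium-richness region: Omega1 where Q >= theta, Omega2 where
    Q < theta.  Under the lke closure the separating set is the line
    s*x + y = p (i.e. x + y = p in scaled coordinates)."""
    Q = quota(x, y, params, closure)
    if math.isinf(Q):
        return "Omega1"
    if abs(Q - params.theta) <= tol:
        return "boundary"
    return "Omega1" if Q >= params.theta else "Omega2"


def classify(model: ModelKind, eq: Equilibrium, params: ModelParams,
             closure: Closure = "qss",
             response: FunctionalResponse | None = None) -> StabilityReport:
    """Build a full stability report for an equilibrium of either model.

    The theorem flags record which nullcline-slope clause the
    configuration matches: for the discrete map, an interior equilibrium
    with the immune nullcline shallower than the tumour's is predicted
    unstable; for the ODE, the slope comparison combined with the
    potassium region drives the saddle clauses.  Verdicts always come
    from the eigenvalues (Jury for the map), never from the flags.
    """
    resp = response if response is not None else make_response(params)
    J = jacobian(model, eq.x, eq.y, params, closure, resp)
    eig = np.linalg.eigvals(J)
    tr = float(np.trace(J))
    det = float(np.linalg.det(J))

    # nullcline slopes come from the continuous partials at the point
    Jc = jacobian("continuous", eq.x, eq.y, params, closure, resp)
    F_x, F_y, G_x, G_y = Jc[0, 0], Jc[0, 1], Jc[1, 0], Jc[1, 1]
    slope_F = -F_x / F_y if F_y != 0 else math.inf * np.sign(-F_x or 1.0)
    slope_G = -G_x / G_y if G_y != 0 else math.inf * np.sign(-G_x or 1.0)
    if math.isclose(slope_G, slope_F, rel_tol=1e-12, abs_tol=1e-12):
        comparison = "equal"
    elif slope_G < slope_F:
        comparison = "immune_smaller"
    else:
        comparison = "immune_greater"

    r = rates_and_partials(eq.x, eq.y, params, closure)
    on_switch = r.on_growth_switch or r.on_efficiency_switch
    region = region_of(eq.x, eq.y, params, closure)

    flags: list[str] = []
    if eq.kind == "internal":
        if model == "discrete" and comparison == "immune_smaller":
            flags.append("discrete_slope_clause_unstable")
        if model == "continuous":
            if region == "Omega1" and comparison == "immune_smaller":
                flags.append("continuous_saddle_clause")
            if region == "Omega2" and comparison == "immune_greater" and G_y > 0:
                flags.append("continuous_saddle_clause")

    if model == "continuous":
        verdict = _continuous_verdict(eig, det)
        jury = None
    else:
        verdict = _discrete_verdict(eig)
        jury = jury_stable(J)

    return StabilityReport(
        model=model, equilibrium=eq, jacobian=J, eigenvalues=eig,
        verdict=verdict, trace=tr, determinant=det, jury_verdict=jury,
        nullcline_slope_tumour=float(slope_F), nullcline_slope_immune=float(slope_G),
        slope_comparison=comparison, region=region, theorem_flags=flags,
        on_switch_surface=bool(on_switch),
    )


def e1_eigenvalue(params: ModelParams, closure: Closure = "qss") -> float:
    """Closed-form tumour-direction eigenvalue at E1 = (0, u/d).

    The Jacobian is triangular at x = 0, so E1's stability is decided by
    b*min(1, 1 - q/Q(0, u/d)) - f'(0)*u/d (the other eigenvalue is -d).
    Negative means the immune standing stock clears incipient tumours
    (elimination); it increases with K_t through Q(0, u/d).
    """
    resp = make_response(params)
    y1 = params.u / params.d
    r = rates_and_partials(0.0, y1, params, closure)
    return r.mu - resp.deriv(0.0) * y1


def e1_scan(params: ModelParams, u_values: Sequence[float],
            K_t_values: Sequence[float], closure: Closure = "qss") -> list[dict]:
    """Scan (u, K_t) and record E1's deciding eigenvalue and stability.

    Recovers empirically the treatment and potassium thresholds for
    elimination: larger u stabilizes E1; larger K_t destabilizes it.
    """
    out = []
    for u in u_values:
        for K_t in K_t_values:
            p = params.replace(u=u, K_t=K_t)
            lam = e1_eigenvalue(p, closure)
            out.append({"u": u, "K_t": K_t, "eigenvalue": lam,
                        "E1_stable": lam < 0,
                        "feasible": p.theta * u / p.d < K_t})
    return out


# ---------------------------------------------------------------------------
# invariant region

@dataclass
class InvarianceReport:
    k: float
    p: float
    s: float
    triangle: bool
    min_margin: float
    worst_edge: str
    verdict: str                    # "invariant" | "violated"
    edge_margins: dict = field(default_factory=dict)
    interior_K_f_min: float = math.nan
    axis_note: str = "x = 0 axis is itself invariant (dx/dt = 0 there)"
    samples: list[dict] = field(default_factory=list)

    def to_dict(self) -> dict:
        d = self.__dict__.copy()
        d.pop("samples")
        return d


def invariance_check(params: ModelParams, closure: Closure = "qss",
                     n_boundary: int = 200, n_interior: int = 200,
                     tol: float = 1e-9, rng: np.random.Generator | None = None,
                     keep_samples: bool = False) -> InvarianceReport:
    """Audit forward invariance of the trapezoid Delta by boundary flux.

    Samples each edge and computes the inward normal component of the
    vector field: bottom edge y = 0 has flux dy/dt = u >= 0; the right
    edge x = k has inward flux -dx/dt; the slanted potassium-ceiling edge
    q*x + theta*y = K_t has inward flux -(q*dx + theta*dy)/|(q, theta)|.
    Also audits K_f >= 0 on interior samples (free potassium can never go
    negative inside Delta under the qss closure).
    """
    geom = trapezoid_vertices(params)
    k, p, s = geom["k"], geom["p"], geom["s"]
    resp = make_response(params)
    rng = rng if rng is not None else np.random.default_rng(0)
    eps = 1e-9

    edges: dict[str, list[float]] = {"bottom": [], "right": [], "slant": []}
    samples: list[dict] = []

    def flux_at(x, y, normal):
        dx, dy = rhs(x, y, params, closure, response=resp, check=False)
        return normal[0] * dx + normal[1] * dy

    norm_qt = math.hypot(params.q, params.theta)
    for i in range(n_boundary):
        frac = (i + 0.5) / n_boundary
        # bottom edge y = 0, 0 < x < k
        xb = frac * k
        edges["bottom"].append(flux_at(xb, 0.0, (0.0, 1.0)))
        # slanted edge q*x + theta*y = K_t (just inside to stay feasible)
        xs_ = frac * k
        ys_ = (params.K_t - params.q * xs_) / params.theta - eps
        if ys_ > 0:
            edges["slant"].append(
                flux_at(xs_, ys_, (-params.q / norm_qt, -params.theta / norm_qt)))
        # right edge x = k, 0 < y < p - s*k (trapezoid only)
        if not geom["triangle"]:
            ymax = p - s * k
            yr = frac * ymax
            edges["right"].append(flux_at(k, yr, (-1.0, 0.0)))
        if keep_samples:
            samples.append({"edge_frac": frac})

    edge_margins = {name: (min(v) if v else math.inf) for name, v in edges.items()}
    min_margin = min(edge_margins.values())
    worst_edge = min(edge_margins, key=edge_margins.get)  # type: ignore[arg-type]

    # interior free-potassium audit
    kf_min = math.inf
    for _ in range(n_interior):
        xi = rng.uniform(0, k)
        yi_max = p - s * xi
        if yi_max <= 0:
            continue
        yi = rng.uniform(0, yi_max)
        kf_min = min(kf_min, free_potassium(xi, yi, params, closure))

    verdict = "invariant" if min_margin >= -tol and kf_min >= -tol else "violated"
    return InvarianceReport(
        k=k, p=p, s=s, triangle=geom["triangle"],
        min_margin=float(min_margin), worst_edge=worst_edge, verdict=verdict,
        edge_margins={n: float(v) for n, v in edge_margins.items()},
        interior_K_f_min=float(kf_min), samples=samples,
    )


# ---------------------------------------------------------------------------
# immunoediting phases

@dataclass
class PhaseResult:
    phase: str           # "elimination" | "equilibrium" | "escape" | "inconclusive"
    subcase: str = ""
    E1_stable: bool | None = None
    internal_equilibria: list[Equilibrium] = field(default_factory=list)
    attractor_summary: dict = field(default_factory=dict)


def classify_phase(params: ModelParams, closure: Closure = "qss",
                   starts: Sequence[tuple[float, float]] | None = None,
                   t_end: float = 800.0, extinction_threshold: float = 1e-6,
                   grid_density: int = 30) -> PhaseResult:
    """Classify the immunoediting phase the parameter set realizes.

    elimination: the tumour-free equilibrium E1 = (0, u/d) is stable and
    every test trajectory drives the tumour below the extinction
    threshold (sustained over the last 10% of the horizon).
    equilibrium: trajectories converge to a stable internal coexistence
    equilibrium E2.  escape: either the tumour-only boundary attractor
    (l = u = 0 reduction) or sustained bounded oscillation of both
    populations around a saddle E2.
    """
    geom = trapezoid_vertices(params)
    k, p, s = geom["k"], geom["p"], geom["s"]
    if starts is None:
        starts = [(0.2 * k, 0.2 * p), (0.6 * k, 0.1 * p), (0.3 * k, 0.5 * p)]
        starts = [(x, min(y, 0.9 * (p - s * x))) for x, y in starts]

    e1 = boundary_equilibrium(params, closure)
    e1_stable = e1_eigenvalue(params, closure) < 0 if e1.feasible else None
    internal = find_internal_equilibria(params, closure, grid_density=grid_density)

    finals, oscillating, extinct = [], 0, 0
    for s0 in starts:
        traj = simulate(s0, t_end, params, closure, rtol=1e-8, atol=1e-10,
                        t_eval=np.linspace(0.0, t_end, 2000))
        tail = traj.t >= 0.9 * t_end
        prev = (traj.t >= 0.8 * t_end) & ~tail
        xt, yt = traj.x[tail], traj.y[tail]
        finals.append((float(xt[-1]), float(yt[-1])))
        if np.all(xt < extinction_threshold):
            extinct += 1
        amp = max(float(xt.max() - xt.min()), float(yt.max() - yt.min()))
        amp_prev = max(float(traj.x[prev].max() - traj.x[prev].min()),
                       float(traj.y[prev].max() - traj.y[prev].min()))
        # sustained oscillation: non-trivial amplitude that is not decaying
        # (a slowly converging focus shrinks window over window)
        if amp > 1e-4 and amp > 0.7 * amp_prev:
            oscillating += 1

    summary = {"finals": finals, "n_oscillating": oscillating, "n_extinct": extinct}

    if e1_stable and extinct == len(starts):
        return PhaseResult("elimination", "tumour cleared to E1", e1_stable,
                           internal, summary)

    stable_internal = [
        e for e in internal
        if classify("continuous", e, params, closure).verdict.startswith("stable")
    ]
    if stable_internal and oscillating == 0:
        for e in stable_internal:
            if any(math.hypot(fx - e.x, fy - e.y) < 1e-3 for fx, fy in finals):
                return PhaseResult("equilibrium", "stable internal coexistence",
                                   e1_stable, internal, summary)

    if params.l == 0 and params.u == 0 and oscillating == 0:
        if any(abs(fx - k) < 1e-3 and fy < extinction_threshold for fx, fy in finals):
            return PhaseResult("escape", "boundary attractor (k, 0)", e1_stable,
                               internal, summary)

    if oscillating > 0:
        bounded = all(fx < 10 * k and fy < 10 * p for fx, fy in finals)
        if bounded:
            return PhaseResult("escape", "sustained oscillatory coexistence",
                               e1_stable, internal, summary)

    # convergence to a point not matching a located stable equilibrium
    if oscillating == 0 and stable_internal:
        return PhaseResult("equilibrium", "stable internal coexistence",
                           e1_stable, internal, summary)
    return PhaseResult("inconclusive", "", e1_stable, internal, summary)
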