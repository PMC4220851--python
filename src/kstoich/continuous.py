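"""Continuous stoichiometric tumour-immune model: quota closure, Liebig
growth law, right-hand side, and trajectory simulation.

State is ``(x, y)``: tumour and immune carbon biomass.  The closed
potassium pool ``K_t = K_c + K_i + K_f`` splits into tumour potassium
``K_c = Q*x``, immune potassium ``K_i = theta*y`` and free potassium
``K_f``.  The tumour quota ``Q`` is eliminated by a quasi-steady-state
closure (mode ``"qss"``)::

    Q(x, y) = (q*mu_m/alpha + K_t - theta*y) / (mu_m/alpha + x)

or by its alpha -> infinity limit (mode ``"lke"``), in which all free
potassium is instantaneously absorbed::

    Q(x, y) = (K_t - theta*y) / x

The tumour grows by Liebig's minimum of a carbon-limited logistic rate and
a potassium-limited Droop rate; the immune population is recruited with an
efficiency that degrades when tumour cells are potassium-poor (Q < theta),
is coerced at rate ``l*x``, dies at rate ``d``, and receives a constant
influx ``u``::

    dx/dt = b*x*min(1 - x/L, 1 - q/Q) - f(x)*y
    dy/dt = e*min(1, Q/theta)*f(x)*y - l*x*y - d*y + u
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np
from scipy.integrate import solve_ivp

from .params import ModelParams
from .response import FunctionalResponse, monod

__all__ = [
    "Closure",
    "FeasibilityError",
    "quota",
    "quota_with_partials",
    "free_potassium",
    "potassium_pools",
    "tumour_growth_factor",
    "recruitment_efficiency",
    "rhs",
    "rates_and_partials",
    "Trajectory",
    "simulate",
    "make_response",
]

Closure = Literal["qss", "lke"]


class FeasibilityError(ValueError):
    """State outside the model's domain (theta*y >= K_t: the immune
    population alone would exceed the closed potassium pool)."""


def make_response(params: ModelParams) -> FunctionalResponse:
    """Default Monod response built from the parameter vector."""
    return monod(a=params.a, c=params.c)


def _check_feasible(x: float, y: float, params: ModelParams) -> None:
    if x < 0 or y < 0:
        raise FeasibilityError(f"state must be nonnegative, got ({x}, {y})")
    if params.theta * y >= params.K_t:
        raise FeasibilityError(
            f"infeasible state: theta*y = {params.theta * y} >= K_t = {params.K_t}")


def quota(x: float, y: float, params: ModelParams, closure: Closure = "qss") -> float:
    """Tumour potassium:carbon quota Q under the chosen closure.

    Under ``lke`` at x = 0 the quota is returned as ``inf`` (its limit),
    which saturates every ``min(., Q/theta)`` branch downstream and keeps
    the right-hand side continuous on the y-axis.
    """
    if closure == "qss":
        m = params.mu_m / params.alpha
        return (params.q * m + params.K_t - params.theta * y) / (m + x)
    elif closure == "lke":
        if x == 0.0:
            return math.inf
        return (params.K_t - params.theta * y) / x
    raise ValueError(f"unknown closure {closure!r}")


def quota_with_partials(x: float, y: float, params: ModelParams,
                        closure: Closure = "qss") -> tuple[float, float, float]:
    """Return (Q, dQ/dx, dQ/dy)."""
    if closure == "qss":
        m = params.mu_m / params.alpha
        denom = m + x
        Q = (params.q * m + params.K_t - params.theta * y) / denom
        return Q, -Q / denom, -params.theta / denom
    elif closure == "lke":
        if x == 0.0:
            return math.inf, 0.0, 0.0
        Q = (params.K_t - params.theta * y) / x
        return Q, -Q / x, -params.theta / x
    raise ValueError(f"unknown closure {closure!r}")


def free_potassium(x: float, y: float, params: ModelParams,
                   closure: Closure = "qss") -> float:
    """Free potassium K_f = K_t - Q*x - theta*y.

    Under the qss closure this reduces algebraically to
    ``(mu_m/alpha)*(K_t - theta*y - q*x)/(mu_m/alpha + x)``, so its sign
    coincides with the invariant-trapezoid constraint s*x + y < p.  Under
    lke all potassium sits in cells and K_f is identically zero.
    """
    if closure == "lke":
        return 0.0
    Q = quota(x, y, params, closure)
    return params.K_t - Q * x - params.theta * y


def potassium_pools(x: float, y: float, params: ModelParams,
                    closure: Closure = "qss") -> dict[str, float]:
    """The three potassium pools; they sum to K_t by construction."""
    Q = quota(x, y, params, closure)
    K_c = (params.K_t - params.theta * y) if (closure == "lke") else Q * x
    K_i = params.theta * y
    return {"K_c": K_c, "K_i": K_i,
            "K_f": params.K_t - K_c - K_i, "K_t": params.K_t}


def tumour_growth_factor(x: float, y: float, params: ModelParams,
                         closure: Closure = "qss") -> float:
    """Per-capita tumour growth rate b*min(1 - x/L, 1 - q/Q) (per day)."""
    _check_feasible(x, y, params)
    Q = quota(x, y, params, closure)
    carbon = 1.0 - x / params.L
    potassium = 1.0 if math.isinf(Q) else 1.0 - params.q / Q
    return params.b * min(carbon, potassium)


def recruitment_efficiency(x: float, y: float, params: ModelParams,
                           closure: Closure = "qss") -> float:
    """Immune recruitment efficiency e*min(1, Q/theta).

    Full efficiency ``e`` while tumour cells are potassium-rich
    (Q >= theta); reduced in proportion to the quota deficit when they are
    potassium-poor.  Continuous across the switch Q = theta.
    """
    _check_feasible(x, y, params)
    Q = quota(x, y, params, closure)
    if math.isinf(Q):
        return params.e
    return params.e * min(1.0, Q / params.theta)


@dataclass
class _Rates:
    """Per-capita rates, branch labels, and analytic partials at a state.

    ``mu`` is the Liebig growth rate b*min(...); ``eff`` the recruitment
    efficiency e*min(1, Q/theta).  Partials are one-sided on the active
    branch when the state lies on a switch surface (``on_switch`` flags).
    """

    Q: float
    mu: float
    mu_x: float
    mu_y: float
    eff: float
    eff_x: float
    eff_y: float
    limiting_branch: str       # "carbon" | "potassium"
    efficiency_branch: str     # "rich" | "poor"
    on_growth_switch: bool
    on_efficiency_switch: bool


_SWITCH_TOL = 1e-12


def rates_and_partials(x: float, y: float, params: ModelParams,
                       closure: Closure = "qss") -> _Rates:
    """Evaluate the two per-capita rate factors and their state partials."""
    Q, Qx, Qy = quota_with_partials(x, y, params, closure)
    b = params.b

    carbon = 1.0 - x / params.L
    if math.isinf(Q):
        potassium = 1.0
        pot_x = pot_y = 0.0
    else:
        potassium = 1.0 - params.q / Q
        pot_x = params.q * Qx / (Q * Q)
        pot_y = params.q * Qy / (Q * Q)
    on_growth_switch = abs(carbon - potassium) <= _SWITCH_TOL * max(1.0, abs(carbon))
    if carbon <= potassium:
        mu, mu_x, mu_y = b * carbon, -b / params.L, 0.0
        limiting = "carbon"
    else:
        mu, mu_x, mu_y = b * potassium, b * pot_x, b * pot_y
        limiting = "potassium"

    if math.isinf(Q):
        eff, eff_x, eff_y = params.e, 0.0, 0.0
        eff_branch, on_eff_switch = "rich", False
    else:
        ratio = Q / params.theta
        on_eff_switch = abs(ratio - 1.0) <= _SWITCH_TOL
        if ratio >= 1.0:
            eff, eff_x, eff_y = params.e, 0.0, 0.0
            eff_branch = "rich"
        else:
            eff = params.e * ratio
            eff_x = params.e * Qx / params.theta
            eff_y = params.e * Qy / params.theta
            eff_branch = "poor"

    return _Rates(Q=Q, mu=mu, mu_x=mu_x, mu_y=mu_y,
                  eff=eff, eff_x=eff_x, eff_y=eff_y,
                  limiting_branch=limiting, efficiency_branch=eff_branch,
                  on_growth_switch=on_growth_switch,
                  on_efficiency_switch=on_eff_switch)


def rhs(x: float, y: float, params: ModelParams, closure: Closure = "qss",
        response: FunctionalResponse | None = None,
        check: bool = True) -> tuple[float, float]:
    """Right-hand side (dx/dt, dy/dt) of the continuous model."""
    if check:
        _check_feasible(x, y, params)
    resp = response if response is not None else make_response(params)
    r = rates_and_partials(x, y, params, closure)
    fx = resp(x)
    dx = r.mu * x - fx * y
    dy = r.eff * fx * y - params.l * x * y - params.d * y + params.u
    return dx, dy


@dataclass
class Trajectory:
    """A continuous-time solution path with stoichiometric bookkeeping."""

    t: np.ndarray
    x: np.ndarray
    y: np.ndarray
    params: ModelParams
    closure: Closure
    Q: np.ndarray = field(default=None)            # type: ignore[assignment]
    K_f: np.ndarray = field(default=None)          # type: ignore[assignment]
    limiting_branch: list[str] = field(default_factory=list)
    efficiency_branch: list[str] = field(default_factory=list)
    switch_crossings: list[dict] = field(default_factory=list)
    clipped_points: int = 0
    solver: dict = field(default_factory=dict)

    @property
    def final_state(self) -> tuple[float, float]:
        return float(self.x[-1]), float(self.y[-1])

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({
            "t": self.t, "x": self.x, "y": self.y,
            "Q": self.Q, "K_f": self.K_f,
            "limiting_branch": self.limiting_branch,
            "efficiency_branch": self.efficiency_branch,
        })

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


class SolverError(RuntimeError):
    def __init__(self, message: str, last_state: tuple[float, float, float]):
        super().__init__(message)
        self.last_state = last_state


def simulate(state0: tuple[float, float], t_end: float, params: ModelParams,
             closure: Closure = "qss", *, rtol: float = 1e-8, atol: float = 1e-10,
             t_eval: np.ndarray | None = None, max_step: float = np.inf,
             method: str = "LSODA",
             response: FunctionalResponse | None = None) -> Trajectory:
    """Integrate the model from ``state0`` over ``[0, t_end]``.

    The vector field is continuous with kinks on two switch surfaces
    (carbon vs potassium limitation; quota-rich vs quota-poor recruitment),
    so an adaptive solver with tight tolerances suffices; crossings are
    detected post hoc by monitoring the branch labels.  Components that go
    negative by less than ``atol`` are clipped to zero and counted.
    """
    x0, y0 = state0
    _check_feasible(x0, y0, params)
    if t_end <= 0:
        raise ValueError("t_end must be positive")
    resp = response if response is not None else make_response(params)

    def f(t, state):
        return rhs(max(state[0], 0.0), max(state[1], 0.0), params, closure,
                   response=resp, check=False)

    sol = solve_ivp(f, (0.0, float(t_end)), [x0, y0], method=method,
                    rtol=rtol, atol=atol, t_eval=t_eval, max_step=max_step)
    if not sol.success:
        raise SolverError(f"integration failed: {sol.message}",
                          (float(sol.t[-1]), float(sol.y[0, -1]), float(sol.y[1, -1])))

    x = sol.y[0].copy()
    y = sol.y[1].copy()
    clipped = int(np.sum((x < 0) & (x > -atol)) + np.sum((y < 0) & (y > -atol)))
    x[(x < 0) & (x > -atol)] = 0.0
    y[(y < 0) & (y > -atol)] = 0.0

    n = len(sol.t)
    Q = np.empty(n)
    K_f = np.empty(n)
    limiting: list[str] = []
    eff_branch: list[str] = []
    for i in range(n):
        r = rates_and_partials(x[i], y[i], params, closure)
        Q[i] = r.Q
        K_f[i] = free_potassium(x[i], y[i], params, closure)
        limiting.append(r.limiting_branch)
        eff_branch.append(r.efficiency_branch)

    crossings = []
    for i in range(1, n):
        if limiting[i] != limiting[i - 1]:
            crossings.append({"t": float(sol.t[i]), "surface": "liebig",
                              "from": limiting[i - 1], "to": limiting[i]})
        if eff_branch[i] != eff_branch[i - 1]:
            crossings.append({"t": float(sol.t[i]), "surface": "quota",
                              "from": eff_branch[i - 1], "to": eff_branch[i]})

    return Trajectory(
        t=sol.t, x=x, y=y, params=params, closure=closure, Q=Q, K_f=K_f,
        limiting_branch=limiting, efficiency_branch=eff_branch,
        switch_crossings=crossings, clipped_points=clipped,
        solver={"method": method, "rtol": rtol, "atol": atol,
                "nfev": int(sol.nfev), "status": int(sol.status)},
    )
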