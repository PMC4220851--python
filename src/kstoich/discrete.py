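"""Discrete exponential-map analogue of the continuous model.

The map freezes the continuous model's per-capita growth rates over each
unit time interval and integrates exactly, giving::

    x' = x * exp( mu(x, y) - P(x)*y )
    y' = y * exp( eff(x, y)*f(x) - l*x - d + u/y )

with ``mu`` the Liebig growth rate, ``eff`` the recruitment efficiency,
``P(x) = f(x)/x`` (extended by f'(0) at x = 0) and ``u/y`` the influx
expressed per capita at the start of the interval.  The map shares every
equilibrium with the ODE (the exponents vanish exactly where the
per-capita rates do) but, being an exponential map, can period-double
into chaos where the ODE settles to a point.

An alternative variant integrates the constant influx exactly instead of
freezing it per capita (``influx="exact"``); it also shares the ODE's
fixed points.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Literal

import numpy as np

from .continuous import Closure, FeasibilityError, make_response, rates_and_partials
from .params import ModelParams
from .response import FunctionalResponse

__all__ = ["step", "step_with_jacobian", "orbit", "Orbit", "per_capita_rates"]

#: Exponent magnitude cap: beyond this the multiplier is astronomically
#: large/small anyway and exp() would overflow; capped steps are counted.
EXP_CAP = 50.0


def per_capita_rates(x: float, y: float, params: ModelParams,
                     closure: Closure = "qss",
                     response: FunctionalResponse | None = None) -> tuple[float, float]:
    """The frozen per-capita rates (g_x, g_y) exponentiated by the map."""
    if params.theta * y >= params.K_t:
        raise FeasibilityError(
            f"infeasible state: theta*y = {params.theta * y} >= K_t = {params.K_t}")
    if y <= 0 and params.u > 0:
        raise FeasibilityError("per-capita influx u/y undefined at y = 0 with u > 0")
    resp = response if response is not None else make_response(params)
    r = rates_and_partials(x, y, params, closure)
    g_x = r.mu - resp.P(x) * y
    g_y = r.eff * resp(x) - params.l * x - params.d + (params.u / y if y > 0 else 0.0)
    return g_x, g_y


def _capped_exp(g: float) -> tuple[float, bool]:
    if abs(g) > EXP_CAP:
        return math.exp(math.copysign(EXP_CAP, g)), True
    return math.exp(g), False


def step(x: float, y: float, params: ModelParams, closure: Closure = "qss",
         response: FunctionalResponse | None = None,
         influx: Literal["frozen", "exact"] = "frozen") -> tuple[float, float]:
    """One iterate of the discrete map.

    ``x = 0`` maps to ``x' = 0`` exactly (the multiplier uses
    P(0) = f'(0)).  With ``influx="exact"`` the linear per-capita part of
    the immune equation is frozen and the constant influx integrated
    exactly: ``y' = y*e^g + u*(e^g - 1)/g``.
    """
    resp = response if response is not None else make_response(params)
    if influx == "frozen":
        g_x, g_y = per_capita_rates(x, y, params, closure, resp)
        ex, _ = _capped_exp(g_x)
        ey, _ = _capped_exp(g_y)
        return x * ex, y * ey
    elif influx == "exact":
        if params.theta * y >= params.K_t:
            raise FeasibilityError("infeasible state")
        r = rates_and_partials(x, y, params, closure)
        g_x = r.mu - resp.P(x) * y
        g = r.eff * resp(x) - params.l * x - params.d
        ex, _ = _capped_exp(g_x)
        eg, _ = _capped_exp(g)
        if abs(g) < 1e-12:
            y_new = y * eg + params.u * (1.0 + g / 2.0)
        else:
            y_new = y * eg + params.u * (eg - 1.0) / g
        return x * ex, y_new
    raise ValueError(f"unknown influx variant {influx!r}")


def step_with_jacobian(x: float, y: float, params: ModelParams,
                       closure: Closure = "qss",
                       response: FunctionalResponse | None = None
                       ) -> tuple[tuple[float, float], np.ndarray]:
    """One iterate plus the analytic Jacobian of the map at (x, y).

    With R = x*e^{g_x}, S = y*e^{g_y}:

        R_x = e^{g_x} (1 + x dg_x/dx)   R_y = x e^{g_x} dg_x/dy
        S_x = y e^{g_y} dg_y/dx         S_y = e^{g_y} (1 + y dg_y/dy)
    """
    resp = response if response is not None else make_response(params)
    if params.theta * y >= params.K_t:
        raise FeasibilityError("infeasible state")
    if y <= 0 and params.u > 0:
        raise FeasibilityError("per-capita influx u/y undefined at y = 0 with u > 0")
    r = rates_and_partials(x, y, params, closure)
    P, dP = resp.P(x), resp.dP(x)
    fx, dfx = resp(x), resp.deriv(x)

    g_x = r.mu - P * y
    g_y = r.eff * fx - params.l * x - params.d + (params.u / y if y > 0 else 0.0)
    gx_x = r.mu_x - dP * y
    gx_y = r.mu_y - P
    gy_x = r.eff_x * fx + r.eff * dfx - params.l
    gy_y = r.eff_y * fx - (params.u / (y * y) if y > 0 else 0.0)

    ex, _ = _capped_exp(g_x)
    ey, _ = _capped_exp(g_y)
    J = np.array([
        [ex * (1.0 + x * gx_x), x * ex * gx_y],
        [y * ey * gy_x, ey * (1.0 + y * gy_y)],
    ])
    return (x * ex, y * ey), J


@dataclass
class Orbit:
    """A discrete-map iterate sequence with burn-in bookkeeping."""

    x: np.ndarray
    y: np.ndarray
    burn_in: int
    params: ModelParams
    closure: Closure
    capped_steps: int = 0

    @property
    def n(self) -> np.ndarray:
        return np.arange(len(self.x))

    @property
    def post_transient(self) -> tuple[np.ndarray, np.ndarray]:
        return self.x[self.burn_in:], self.y[self.burn_in:]

    def to_frame(self):
        import pandas as pd

        return pd.DataFrame({"n": self.n, "x": self.x, "y": self.y,
                             "transient": self.n < self.burn_in})

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def orbit(state0: tuple[float, float], N: int, burn_in: int = 0,
          params: ModelParams | None = None, closure: Closure = "qss",
          response: FunctionalResponse | None = None,
          influx: Literal["frozen", "exact"] = "frozen") -> Orbit:
    """Iterate the map N times from ``state0`` (iterate 0 = the start)."""
    if params is None:
        raise ValueError("params is required")
    if not (N > burn_in >= 0):
        raise ValueError(f"need N > burn_in >= 0, got N={N}, burn_in={burn_in}")
    resp = response if response is not None else make_response(params)
    xs = np.empty(N + 1)
    ys = np.empty(N + 1)
    xs[0], ys[0] = state0
    capped = 0
    x, y = float(state0[0]), float(state0[1])
    for i in range(1, N + 1):
        try:
            if influx == "frozen":
                g_x, g_y = per_capita_rates(x, y, params, closure, resp)
                ex, c1 = _capped_exp(g_x)
                ey, c2 = _capped_exp(g_y)
                capped += c1 + c2
                x, y = x * ex, y * ey
            else:
                x, y = step(x, y, params, closure, resp, influx=influx)
        except FeasibilityError as err:
            raise FeasibilityError(f"orbit failed at iterate {i}: {err}") from err
        xs[i], ys[i] = x, y
    return Orbit(x=xs, y=ys, burn_in=burn_in, params=params,
                 closure=closure, capped_steps=capped)
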