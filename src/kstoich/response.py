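"""Immune functional responses f(x) and the contract they must satisfy.

The per-immune-cell kill rate f(x) must be a bounded smooth function with
f(0) = 0, f' > 0, and a strictly decreasing per-tumour-biomass rate
P(x) = f(x)/x whose x -> 0+ limit equals f'(0).  All shipped numerics use
the Monod (Holling type II) form c*x/(a + x); other responses can be
plugged in and audited numerically against the same contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable

import numpy as np

__all__ = ["FunctionalResponse", "monod", "linear_response", "response_audit", "AuditReport"]


def _central_diff(f: Callable[[float], float], x: float) -> float:
    h = max(1e-6, 1e-6 * abs(x))
    return (f(x + h) - f(max(x - h, 0.0))) / (x + h - max(x - h, 0.0))


@dataclass(frozen=True)
class FunctionalResponse:
    """A functional response: evaluator, derivative, and P(x) = f(x)/x.

    ``df`` defaults to central differences when no analytic derivative is
    supplied.  ``P(0)`` is defined by its limit f'(0), and ``dP(0)`` by a
    one-sided difference, so the response is usable on the whole axis
    x >= 0.
    """

    f: Callable[[float], float]
    df: Callable[[float], float] | None = None
    name: str = "custom"
    params: dict = field(default_factory=dict)

    def __call__(self, x: float) -> float:
        if x < 0:
            raise ValueError(f"functional response needs x >= 0, got {x}")
        return self.f(x)

    def deriv(self, x: float) -> float:
        if self.df is not None:
            return self.df(x)
        return _central_diff(self.f, x)

    def P(self, x: float) -> float:
        """Per-tumour-biomass kill rate f(x)/x, extended by f'(0) at x=0."""
        if x < 0:
            raise ValueError(f"P(x) needs x >= 0, got {x}")
        if x == 0.0:
            return self.deriv(0.0)
        return self.f(x) / x

    def dP(self, x: float) -> float:
        if x == 0.0:
            h = 1e-6
            return (self.P(h) - self.P(0.0)) / h
        if self.df is not None:
            return (self.deriv(x) * x - self.f(x)) / (x * x)
        return _central_diff(self.P, x)


class MonodResponse(FunctionalResponse):
    """Monod / Holling II response with exact P and derivatives."""

    def __init__(self, a: float, c: float):
        if a <= 0 or c <= 0:
            raise ValueError("monod response needs a > 0 and c > 0")
        super().__init__(
            f=lambda x: c * x / (a + x),
            df=lambda x: c * a / (a + x) ** 2,
            name="monod",
            params={"a": a, "c": c},
        )
        object.__setattr__(self, "a", a)
        object.__setattr__(self, "c", c)

    def P(self, x: float) -> float:
        if x < 0:
            raise ValueError(f"P(x) needs x >= 0, got {x}")
        return self.c / (self.a + x)

    def dP(self, x: float) -> float:
        return -self.c / (self.a + x) ** 2


def monod(a: float = 0.25, c: float = 0.81) -> MonodResponse:
    """Monod response c*x/(a+x): saturating at c, half-saturation at x=a."""
    return MonodResponse(a=a, c=c)


def linear_response(c: float) -> FunctionalResponse:
    """Unbounded mass-action response c*x (fails the boundedness contract;
    provided for audits and comparisons only)."""
    return FunctionalResponse(f=lambda x: c * x, df=lambda x: c,
                              name="linear", params={"c": c})


@dataclass(frozen=True)
class AuditReport:
    """Pass/fail per contract property, evaluated numerically on a grid."""

    zero_at_origin: bool
    increasing: bool
    bounded: bool
    P_decreasing: bool
    P_limit_matches_slope: bool
    details: dict = field(default_factory=dict)

    @property
    def all_pass(self) -> bool:
        return (self.zero_at_origin and self.increasing and self.bounded
                and self.P_decreasing and self.P_limit_matches_slope)


def response_audit(resp: FunctionalResponse, grid: np.ndarray,
                   *, bound_factor: float = 20.0, rel_tol: float = 1e-3) -> AuditReport:
    """Numerically audit a functional response against its contract.

    Checks, on the supplied strictly positive sorted grid: f(0+) -> 0,
    monotone increase of f, boundedness (no blow-up: the largest value may
    not exceed ``bound_factor`` times the value at the grid median),
    monotone decrease of P(x) = f(x)/x, and agreement of the P(0+) limit
    with f'(0).
    """
    grid = np.asarray(grid, dtype=float)
    if grid.size == 0:
        raise ValueError("response_audit needs a non-empty grid")
    if np.any(grid <= 0) or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be strictly positive and strictly increasing")

    fv = np.array([resp(x) for x in grid])
    Pv = np.array([resp.P(x) for x in grid])

    zero_at_origin = abs(resp(0.0)) <= 1e-12 and fv[0] <= resp.deriv(0.0) * grid[0] * 2 + 1e-12
    increasing = bool(np.all(np.diff(fv) > -1e-12 * np.maximum(fv[:-1], 1.0)))
    mid = fv[len(fv) // 2]
    bounded = bool(fv[-1] <= bound_factor * max(mid, 1e-300))
    P_decreasing = bool(np.all(np.diff(Pv) < 1e-12 * np.maximum(Pv[:-1], 1.0)))
    slope0 = resp.deriv(0.0)
    P0 = resp.P(grid[0] * 1e-3) if grid[0] > 1e-290 else resp.P(grid[0])
    P_limit = abs(P0 - slope0) <= rel_tol * max(abs(slope0), 1e-12)

    return AuditReport(
        zero_at_origin=bool(zero_at_origin),
        increasing=increasing,
        bounded=bounded,
        P_decreasing=P_decreasing,
        P_limit_matches_slope=bool(P_limit),
        details={"f_max": float(fv[-1]), "slope0": float(slope0), "P_first": float(Pv[0])},
    )
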