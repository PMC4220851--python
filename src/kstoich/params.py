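"""Model parameter vectors, validation, and the potassium-scaled form.

The model couples a tumour cell population (prey, biomass ``x``) to a
cytotoxic immune cell population (predator, biomass ``y``) in a closed
potassium (K+) pool of total mass ``K_t``.  Tumour cells carry a variable
potassium:carbon quota ``Q`` with floor ``q``; immune cells keep a fixed
quota ``theta``.  The scaled form trades ``(K_t, q, theta)`` for
``p = K_t/theta`` (the maximal immune density the potassium pool can
support) and ``s = q/theta`` (dimensionless quota ratio), removing the
theta gauge from the equations.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from typing import Any

__all__ = [
    "ModelParams",
    "ScaledParams",
    "Diagnostic",
    "reference_parameters",
    "scale",
    "unscale",
    "validate",
    "REFERENCE_L_RANGE",
]

#: Admissible carrying-capacity range of the reference set (carbon biomass).
REFERENCE_L_RANGE = (0.25, 2.0)


class InvalidParameterError(ValueError):
    """A parameter value makes the model ill-defined (e.g. theta = 0)."""


@dataclass(frozen=True)
class ModelParams:
    """Full parameter vector of the stoichiometric tumour-immune model.

    Parameters
    ----------
    b : tumour intrinsic growth rate (per day).
    L : carbon-limited tumour carrying capacity (carbon biomass).
    K_t : total potassium mass in the closed system.
    theta : fixed immune-cell potassium:carbon quota (dimensionless).
    q : tumour minimal potassium:carbon quota (dimensionless).
    mu_m : tumour true maximal growth rate (per day).
    alpha : potassium uptake proportionality constant (per day).
    e : maximal immune recruitment efficiency (dimensionless, <= 1).
    d : immune apoptosis rate (per day).
    l : coercion rate coefficient (per biomass per day); loss of immune
        cells recruited by the tumour into a tumour-promoting role.
    u : constant immune-cell influx (biomass per day); a treatment
        surrogate.  With ``u > 0`` the model has the boundary equilibrium
        ``(0, u/d)``.
    c : maximal per-capita kill rate of the functional response (per day).
    a : half-saturation biomass of the functional response.
    """

    b: float = 1.2
    L: float = 1.0
    K_t: float = 0.025
    theta: float = 0.03
    q: float = 0.0038
    mu_m: float = 1.2
    alpha: float = 10.0
    e: float = 0.8
    d: float = 0.25
    l: float = 0.0
    u: float = 0.0
    c: float = 0.81
    a: float = 0.25

    def replace(self, **kwargs: float) -> "ModelParams":
        return dataclasses.replace(self, **kwargs)

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)

    @classmethod
    def from_dict(cls, d: dict[str, float]) -> "ModelParams":
        unknown = set(d) - {f.name for f in dataclasses.fields(cls)}
        if unknown:
            raise InvalidParameterError(f"unknown parameter keys: {sorted(unknown)}")
        return cls(**d)

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)


@dataclass(frozen=True)
class ScaledParams:
    """Theta-scaled parameter vector.

    ``p = K_t/theta`` is the maximal immune cell density allowed by the
    total potassium; ``s = q/theta`` the quota ratio.  All other fields of
    :class:`ModelParams` are retained unchanged.
    """

    p: float
    s: float
    b: float
    L: float
    mu_m: float
    alpha: float
    e: float
    d: float
    l: float
    u: float
    c: float
    a: float

    def to_dict(self) -> dict[str, float]:
        return dataclasses.asdict(self)


@dataclass(frozen=True)
class Diagnostic:
    """One validation finding: ``severity`` is ``"error"`` or ``"warning"``."""

    severity: str
    field: str
    message: str

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return f"[{self.severity}] {self.field}: {self.message}"


def reference_parameters(L_choice: float = 1.0, *, l: float = 0.0, u: float = 0.0,
                         warn: bool = True) -> ModelParams:
    """Return the reference parameter set with carrying capacity ``L_choice``.

    The reference values mimic laboratory stoichiometric grazer experiments
    and are the set all shipped scenarios start from.  The carrying
    capacity is given as a range (0.25-2.0) rather than a point value and
    must be chosen; the coercion rate ``l`` and treatment influx ``u`` are
    scenario-specific and default to zero (the plain stoichiometric
    predator-prey reduction).
    """
    lo, hi = REFERENCE_L_RANGE
    if warn and not (lo <= L_choice <= hi):
        import warnings

        warnings.warn(
            f"L_choice={L_choice} outside the reference range {REFERENCE_L_RANGE}",
            stacklevel=2,
        )
    return ModelParams(L=float(L_choice), l=float(l), u=float(u))


def scale(params: ModelParams) -> ScaledParams:
    """Scale theta out: ``p = K_t/theta``, ``s = q/theta``; rest copied."""
    if params.theta <= 0:
        raise InvalidParameterError("theta must be strictly positive to scale")
    return ScaledParams(
        p=params.K_t / params.theta,
        s=params.q / params.theta,
        b=params.b, L=params.L, mu_m=params.mu_m, alpha=params.alpha,
        e=params.e, d=params.d, l=params.l, u=params.u,
        c=params.c, a=params.a,
    )


def unscale(scaled: ScaledParams, theta: float = 1.0) -> ModelParams:
    """Rebuild a :class:`ModelParams` from the scaled form and a theta gauge.

    Any ``theta > 0`` gives an equivalent model: ``K_t = p*theta`` and
    ``q = s*theta``, so re-scaling reproduces the same :class:`ScaledParams`.
    """
    if theta <= 0:
        raise InvalidParameterError("theta must be strictly positive")
    return ModelParams(
        K_t=scaled.p * theta, q=scaled.s * theta, theta=theta,
        b=scaled.b, L=scaled.L, mu_m=scaled.mu_m, alpha=scaled.alpha,
        e=scaled.e, d=scaled.d, l=scaled.l, u=scaled.u,
        c=scaled.c, a=scaled.a,
    )


_STRICTLY_POSITIVE = ("b", "d", "theta", "q", "mu_m", "alpha", "c", "a", "L")
_NONNEGATIVE = ("K_t", "e", "l", "u")


def validate(params: ModelParams) -> list[Diagnostic]:
    """Check the parameter invariants; return diagnostics (empty = valid).

    Errors (model ill-defined) and warnings (unusual regime) are returned
    as values, never raised, so callers can report all findings at once.
    """
    out: list[Diagnostic] = []
    for name in _STRICTLY_POSITIVE:
        v = getattr(params, name)
        if not v > 0:
            out.append(Diagnostic("error", name, f"{name} must be positive (got {v})"))
    for name in _NONNEGATIVE:
        v = getattr(params, name)
        if v < 0:
            out.append(Diagnostic("error", name, f"{name} must be nonnegative (got {v})"))
    if params.theta > 0 and params.q >= params.theta:
        out.append(Diagnostic(
            "warning", "q",
            "q >= theta: s >= 1; invariant region becomes degenerate"))
    if params.e > 1:
        out.append(Diagnostic(
            "warning", "e", f"recruitment efficiency e={params.e} > 1 is unusual"))
    return out


def has_errors(diagnostics: list[Diagnostic]) -> bool:
    return any(d.severity == "error" for d in diagnostics)
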