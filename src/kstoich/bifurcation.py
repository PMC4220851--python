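"""One-parameter bifurcation sweeps, period detection, and Lyapunov
exponents for the continuous model and its discrete analogue.

A sweep varies one parameter over a grid, runs each model past its
transient, and records attractor samples: post-burn-in iterates for the
map, post-transient trajectory extrema for the ODE.  Period estimation is
by near-recurrence of the sample sequence; the maximal Lyapunov exponent
of the map is the average log growth of a tangent vector propagated by
the analytic Jacobian with periodic renormalization.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Callable, Literal, Sequence

import numpy as np

from .continuous import Closure, simulate
from .discrete import orbit, step_with_jacobian
from .params import ModelParams

__all__ = ["SweepProtocol", "BifurcationDiagram", "sweep", "detect_period",
           "lyapunov_max", "lyapunov_max_model"]


@dataclass(frozen=True)
class SweepProtocol:
    """Transient and sampling protocol for a sweep.

    Discrete: discard ``burn_in`` iterates, keep ``n_samples``.
    Continuous: integrate ``transient`` days, then record over ``record``
    days at spacing ``dt`` and keep extrema plus the last ``n_samples``
    points.  Warm start (default) carries the final state of each
    parameter value to the next; cold start reuses ``state0``.
    """

    burn_in: int = 2000
    n_samples: int = 300
    transient: float = 500.0
    record: float = 200.0
    dt: float = 0.1
    warm_start: bool = True
    state0: tuple[float, float] = (0.3, 0.3)
    lyapunov: bool = True
    lyapunov_iters: int = 2000
    point_tol: float = 1e-5


@dataclass
class BifurcationDiagram:
    model: Literal["continuous", "discrete"]
    param_name: str
    values: np.ndarray
    samples: list[dict]          # per value: {"x": array, "y": array}
    periods: list[int]
    lyapunov: list[float]        # nan for continuous / disabled
    extrema: list[dict]          # per value: min/max of each variable
    failures: list[dict]
    protocol: SweepProtocol = field(default=None)  # type: ignore[assignment]
    closure: Closure = "qss"

    def to_frame(self):
        import pandas as pd

        rows = []
        for i, v in enumerate(self.values):
            per = self.periods[i]
            lya = self.lyapunov[i]
            for var in ("x", "y"):
                for s in np.atleast_1d(self.samples[i][var]):
                    rows.append({"param": self.param_name, "value": v,
                                 "variable": var, "sample": s,
                                 "period": per, "lyapunov": lya})
        return pd.DataFrame(rows)

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)


def detect_period(samples: np.ndarray, tol: float = 1e-4,
                  max_period: int = 64) -> int:
    """Smallest k with ||s[n+k] - s[n]|| < tol for all n; 0 if aperiodic.

    ``samples`` may be 1-D or (n, d); needs at least 2*max_period points
    to test the largest period.
    """
    samples = np.asarray(samples, dtype=float)
    if samples.ndim == 1:
        samples = samples[:, None]
    n = len(samples)
    if n < 2 * max_period:
        raise ValueError(f"need >= {2 * max_period} samples, got {n}")
    for k in range(1, max_period + 1):
        if np.max(np.abs(samples[k:] - samples[:-k])) < tol:
            return k
    return 0


def lyapunov_max(map_with_jac: Callable[[np.ndarray], tuple[np.ndarray, np.ndarray]],
                 state0: Sequence[float], N: int = 2000, burn_in: int = 200,
                 renorm_every: int = 1) -> float:
    """Maximal Lyapunov exponent of a map given state -> (next, Jacobian).

    Propagates a tangent vector through the Jacobian chain, renormalizing
    every ``renorm_every`` steps, and averages the log stretching over the
    post-burn-in iterates.
    """
    if N < 10:
        raise ValueError("need N >= 10 iterates")
    state = np.asarray(state0, dtype=float)
    v = np.ones_like(state) / math.sqrt(len(state))
    log_sum = 0.0
    count = 0
    for i in range(N):
        state, J = map_with_jac(state)
        if not np.all(np.isfinite(state)):
            raise RuntimeError(f"orbit escaped at iterate {i}")
        v = np.asarray(J) @ v
        if (i + 1) % renorm_every == 0:
            norm = np.linalg.norm(v)
            if norm == 0:
                return -math.inf
            if i >= burn_in:
                log_sum += math.log(norm)
                count += renorm_every
            v /= norm
    if count == 0:
        raise RuntimeError("no post-burn-in iterates accumulated")
    return log_sum / count


def lyapunov_max_model(params: ModelParams, state0: tuple[float, float],
                       N: int = 2000, burn_in: int = 200,
                       closure: Closure = "qss") -> float:
    """Maximal Lyapunov exponent of the discrete tumour-immune map."""

    def f(state):
        (xn, yn), J = step_with_jacobian(state[0], state[1], params, closure)
        return np.array([xn, yn]), J

    return lyapunov_max(f, state0, N=N, burn_in=burn_in)


def _sweep_value_discrete(params: ModelParams, state: tuple[float, float],
                          proto: SweepProtocol, closure: Closure):
    N = proto.burn_in + proto.n_samples
    ob = orbit(state, N, burn_in=proto.burn_in, params=params, closure=closure)
    xs, ys = ob.post_transient
    samples = {"x": xs, "y": ys}
    pts = np.column_stack([xs, ys])
    max_p = min(64, len(pts) // 2)
    period = detect_period(pts, tol=1e-4, max_period=max_p)
    lya = math.nan
    if proto.lyapunov:
        try:
            lya = lyapunov_max_model(params, (float(ob.x[-1]), float(ob.y[-1])),
                                     N=proto.lyapunov_iters, closure=closure)
        except Exception:  # noqa: BLE001 - exponent is optional diagnostics
            lya = math.nan
    final = (float(ob.x[-1]), float(ob.y[-1]))
    extrema = {"x_min": float(xs.min()), "x_max": float(xs.max()),
               "y_min": float(ys.min()), "y_max": float(ys.max())}
    return samples, period, lya, extrema, final


def _sweep_value_continuous(params: ModelParams, state: tuple[float, float],
                            proto: SweepProtocol, closure: Closure):
    t_end = proto.transient + proto.record
    n_eval = int(round(proto.record / proto.dt)) + 1
    t_eval = np.linspace(proto.transient, t_end, n_eval)
    traj = simulate(state, t_end, params, closure, t_eval=t_eval)
    xs, ys = traj.x, traj.y
    extrema = {"x_min": float(xs.min()), "x_max": float(xs.max()),
               "y_min": float(ys.min()), "y_max": float(ys.max())}
    idx = np.linspace(0, len(xs) - 1, min(proto.n_samples, len(xs))).astype(int)
    samples = {"x": xs[idx], "y": ys[idx]}
    ranges = max(extrema["x_max"] - extrema["x_min"],
                 extrema["y_max"] - extrema["y_min"])
    period = 1 if ranges < proto.point_tol else 0
    final = (float(xs[-1]), float(ys[-1]))
    return samples, period, math.nan, extrema, final


def sweep(model: Literal["continuous", "discrete"], param_name: str,
          values: Sequence[float], params: ModelParams,
          closure: Closure = "qss",
          protocol: SweepProtocol | None = None) -> BifurcationDiagram:
    """Run a one-parameter sweep and collect attractor summaries.

    Individual parameter values that fail (e.g. orbit escapes) are logged
    and skipped; the sweep only raises if every value fails.
    """
    if param_name not in params.to_dict():
        raise ValueError(f"unknown parameter {param_name!r}")
    proto = protocol if protocol is not None else SweepProtocol()
    values = np.asarray(values, dtype=float)
    if len(values) > 1 and not np.all(np.diff(values) > 0) \
            and not np.all(np.diff(values) < 0):
        raise ValueError("sweep values must be strictly monotone")

    samples, periods, lyap, extrema, failures = [], [], [], [], []
    state = proto.state0
    runner = _sweep_value_discrete if model == "discrete" else _sweep_value_continuous
    for v in values:
        p = params.replace(**{param_name: float(v)})
        try:
            s, per, ly, ext, final = runner(p, state, proto, closure)
        except Exception as err:  # noqa: BLE001 - per-value failures logged
            failures.append({"value": float(v), "error": str(err)})
            samples.append({"x": np.array([]), "y": np.array([])})
            periods.append(-1)
            lyap.append(math.nan)
            extrema.append({})
            state = proto.state0
            continue
        samples.append(s)
        periods.append(per)
        lyap.append(ly)
        extrema.append(ext)
        if proto.warm_start:
            state = final
    if len(failures) == len(values):
        raise RuntimeError(f"sweep failed at every value: {failures[:3]}...")
    return BifurcationDiagram(
        model=model, param_name=param_name, values=values, samples=samples,
        periods=periods, lyapunov=lyap, extrema=extrema, failures=failures,
        protocol=proto, closure=closure,
    )
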