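"""Scenario configuration: named experiment presets, config loading, and
task execution with structured CSV/JSON outputs.

A scenario bundles a base parameter set (the built-in reference set by
name, or explicit values), field overrides, a quota closure, a task
(simulate | iterate | equilibria | stability | invariance | sweep |
phase) and task options.  Built-in presets encode the two published
experiment families: the carrying-capacity sweeps contrasting total
potassium 0.045 vs 0.06 (fig1A-fig1H) and the growth-rate sweeps where
the discrete map period-doubles into chaos (fig2A, fig2B).
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np

from . import bifurcation, stability
from .continuous import simulate
from .discrete import orbit
from .params import ModelParams, has_errors, validate

__all__ = ["Scenario", "load_scenario", "run_scenario", "builtin_scenarios",
           "SCHEMA_VERSION"]

log = logging.getLogger("kstoich")

SCHEMA_VERSION = 1

_TASKS = {"simulate", "iterate", "equilibria", "stability", "invariance",
          "sweep", "phase"}


@dataclass
class Scenario:
    name: str
    base: str = "table1"
    overrides: dict[str, float] = field(default_factory=dict)
    closure: str = "qss"
    task: str = "simulate"
    options: dict[str, Any] = field(default_factory=dict)

    def resolve_params(self) -> ModelParams:
        if self.base != "table1":
            raise ValueError(f"unknown base parameter set {self.base!r}")
        params = ModelParams()
        if self.overrides:
            params = params.replace(**{k: float(v) for k, v in self.overrides.items()})
        diags = validate(params)
        if has_errors(diags):
            raise ValueError(f"scenario {self.name!r} fails validation: "
                             + "; ".join(str(d) for d in diags))
        return params

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def save(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2, sort_keys=True))


def _fig1(name: str, model: str, K_t: float, variable: str) -> Scenario:
    return Scenario(
        name=name, overrides={"l": 0.2, "u": 0.05, "K_t": K_t},
        task="sweep",
        options={"model": model, "param": "L", "start": 0.25, "stop": 2.0,
                 "n_values": 200, "variable": variable},
    )


def builtin_scenarios() -> dict[str, Scenario]:
    """The shipped presets, keyed by name."""
    out = {
        "fig1A": _fig1("fig1A", "continuous", 0.045, "x"),
        "fig1B": _fig1("fig1B", "discrete", 0.045, "x"),
        "fig1C": _fig1("fig1C", "continuous", 0.045, "y"),
        "fig1D": _fig1("fig1D", "discrete", 0.045, "y"),
        "fig1E": _fig1("fig1E", "continuous", 0.06, "x"),
        "fig1F": _fig1("fig1F", "discrete", 0.06, "x"),
        "fig1G": _fig1("fig1G", "continuous", 0.06, "y"),
        "fig1H": _fig1("fig1H", "discrete", 0.06, "y"),
        "fig2A": Scenario(
            name="fig2A", overrides={"l": 0.009, "u": 0.02, "L": 1.6},
            task="sweep",
            options={"model": "continuous", "param": "b", "start": 0.8,
                     "stop": 3.5, "n_values": 200, "variable": "x"}),
        "fig2B": Scenario(
            name="fig2B", overrides={"l": 0.009, "u": 0.02, "L": 1.6},
            task="sweep",
            options={"model": "discrete", "param": "b", "start": 0.8,
                     "stop": 3.5, "n_values": 200, "variable": "x"}),
        "table1-equilibria": Scenario(
            name="table1-equilibria", overrides={"l": 0.2, "u": 0.05, "L": 1.0},
            task="equilibria", options={}),
        "khe-equilibria": Scenario(
            name="khe-equilibria", overrides={"l": 0.0, "u": 0.0, "L": 1.0},
            task="equilibria", options={}),
        "table1-invariance": Scenario(
            name="table1-invariance", overrides={"l": 0.0, "u": 0.0, "L": 1.0},
            task="invariance", options={}),
    }
    return out


_PARAM_FIELDS = {f.name for f in dataclasses.fields(ModelParams)}


def load_scenario(source) -> Scenario:
    """Load a scenario from a built-in name, a JSON/TOML file, or a dict."""
    if isinstance(source, Scenario):
        return source
    if isinstance(source, dict):
        data = source
    else:
        builtins = builtin_scenarios()
        if str(source) in builtins:
            return builtins[str(source)]
        path = Path(source)
        if not path.exists():
            raise FileNotFoundError(
                f"no built-in scenario or file named {source!r}; "
                f"built-ins: {sorted(builtins)}")
        text = path.read_text()
        if path.suffix == ".toml":
            import tomllib

            data = tomllib.loads(text)
        else:
            data = json.loads(text)

    known = {f.name for f in dataclasses.fields(Scenario)}
    unknown = set(data) - known
    if unknown:
        raise ValueError(f"unknown scenario keys: {sorted(unknown)}")
    sc = Scenario(**data)
    if sc.task not in _TASKS:
        raise ValueError(f"unknown task {sc.task!r}; one of {sorted(_TASKS)}")
    bad = set(sc.overrides) - _PARAM_FIELDS
    if bad:
        raise ValueError(f"overrides reference unknown parameters: {sorted(bad)}")
    sc.resolve_params()  # raises on validation errors
    return sc


def _write_json(path: Path, payload: dict) -> None:
    payload = {"schema_version": SCHEMA_VERSION, **payload}
    path.write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))


def run_scenario(scenario, out_dir=".") -> dict:
    """Execute a scenario's task; write outputs; return a summary dict."""
    sc = load_scenario(scenario)
    params = sc.resolve_params()
    closure = sc.closure
    opts = sc.options
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stem = out / sc.name
    log.info("running scenario %s (task=%s, closure=%s)", sc.name, sc.task, closure)

    summary: dict[str, Any] = {"scenario": sc.name, "task": sc.task,
                               "closure": closure, "outputs": []}

    if sc.task == "simulate":
        traj = simulate(tuple(opts.get("state0", (0.3, 0.3))),
                        float(opts.get("t_end", 500.0)), params, closure)
        path = stem.with_suffix(".csv")
        traj.to_csv(path)
        summary["outputs"].append(str(path))
        summary["final_state"] = traj.final_state
        summary["switch_crossings"] = len(traj.switch_crossings)

    elif sc.task == "iterate":
        ob = orbit(tuple(opts.get("state0", (0.3, 0.3))),
                   int(opts.get("N", 2300)), int(opts.get("burn_in", 2000)),
                   params, closure)
        path = stem.with_suffix(".csv")
        ob.to_csv(path)
        summary["outputs"].append(str(path))
        summary["final_state"] = (float(ob.x[-1]), float(ob.y[-1]))

    elif sc.task == "equilibria":
        eqs: list[stability.Equilibrium] = []
        if params.l == 0 and params.u == 0:
            eqs.extend(stability.boundary_equilibria_khe(params, closure))
        else:
            eqs.append(stability.boundary_equilibrium(params, closure))
        eqs.extend(stability.find_internal_equilibria(
            params, closure, grid_density=int(opts.get("grid_density", 30))))
        path = stem.with_suffix(".json")
        _write_json(path, {"equilibria": [dataclasses.asdict(e) for e in eqs]})
        summary["outputs"].append(str(path))
        summary["n_boundary"] = sum(e.kind == "boundary" for e in eqs)
        summary["n_internal"] = sum(e.kind == "internal" for e in eqs)

    elif sc.task == "stability":
        eqs = [stability.boundary_equilibrium(params, closure)]
        eqs.extend(stability.find_internal_equilibria(
            params, closure, grid_density=int(opts.get("grid_density", 30))))
        reports = []
        for e in eqs:
            if not e.feasible:
                continue
            for model in ("continuous", "discrete"):
                reports.append(stability.classify(model, e, params, closure).to_dict())
        path = stem.with_suffix(".json")
        _write_json(path, {"reports": reports})
        summary["outputs"].append(str(path))
        summary["verdicts"] = [(r["model"], r["verdict"]) for r in reports]

    elif sc.task == "invariance":
        rep = stability.invariance_check(params, closure)
        path = stem.with_suffix(".json")
        _write_json(path, {"invariance": rep.to_dict()})
        summary["outputs"].append(str(path))
        summary["verdict"] = rep.verdict
        summary["min_margin"] = rep.min_margin

    elif sc.task == "sweep":
        values = np.linspace(float(opts["start"]), float(opts["stop"]),
                             int(opts.get("n_values", 200)))
        proto_kwargs = opts.get("protocol", {})
        proto = bifurcation.SweepProtocol(**proto_kwargs) if proto_kwargs \
            else bifurcation.SweepProtocol()
        diagram = bifurcation.sweep(opts.get("model", "continuous"),
                                    opts["param"], values, params, closure, proto)
        path = stem.with_suffix(".csv")
        diagram.to_csv(path)
        summary["outputs"].append(str(path))
        summary["n_values"] = len(values)
        summary["periods"] = diagram.periods
        summary["n_failures"] = len(diagram.failures)

    elif sc.task == "phase":
        res = stability.classify_phase(params, closure,
                                       t_end=float(opts.get("t_end", 800.0)))
        path = stem.with_suffix(".json")
        _write_json(path, {"phase": res.phase, "subcase": res.subcase,
                           "E1_stable": res.E1_stable,
                           "attractor_summary": res.attractor_summary})
        summary["outputs"].append(str(path))
        summary["phase"] = res.phase

    else:  # pragma: no cover - guarded by load_scenario
        raise ValueError(f"unknown task {sc.task!r}")

    _write_json(stem.with_name(stem.name + "_run.json"), {
        "scenario": sc.to_dict(), "summary": {k: v for k, v in summary.items()
                                              if k != "outputs"}})
    return summary
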