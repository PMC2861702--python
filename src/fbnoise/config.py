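"""Run configuration: YAML loading, validation, fixtures, and dispatch.

One structured YAML document describes one run.  Top-level blocks::

    protocol: timescales | simulate | steady | noiseq | sweep | fdt
              | twotimescale | compare
    model:    {id: <model_id>, params: {..optional overrides..}}
    signal:   {S0, delta, gamma, duration, seed}        # noisy protocols
    options:  protocol-specific settings (theta, grids, replicates, ...)
    seed:     integer                                    # mandatory if stochastic
    output:   directory for artifacts

Validation happens before any computation; unknown keys are rejected with a
path into the document and a closest-match hint.  Every run writes a fully
resolved copy of its configuration (defaults expanded) next to its results,
so any artifact can be regenerated from the sidecar alone.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from difflib import get_close_matches
from importlib import resources
from pathlib import Path

import numpy as np
import yaml

from . import experiments, noisemetrics, timescales
from .analytics import fdt_noise_amplification, two_timescale_zero_order
from .models import available_models, build_model, nominal_params
from .signals import (
    CenteredNoiseSignal,
    CompositeSignal,
    ConstantSignal,
    PiecewiseNoiseSignal,
)
from .simulate import integrate

__all__ = ["RunConfig", "ConfigError", "load_config", "run",
           "fixture_names", "load_fixture"]

PROTOCOLS = ("simulate", "steady", "timescales", "noiseq", "sweep", "fdt",
             "twotimescale", "compare")

_TOP_KEYS = {"protocol", "model", "signal", "options", "seed", "output"}
_STOCHASTIC = {"simulate", "noiseq", "sweep", "twotimescale"}

_OPTION_KEYS = {
    "simulate": {"duration", "initial_state", "rtol", "atol"},
    "steady": {"S_low", "S_high"},
    "timescales": {"S_low", "S_high", "theta", "gamma", "convention"},
    "noiseq": {"n_reps", "window_periods", "samples_per_period", "S_low"},
    "sweep": {"param", "grid", "fold", "n_grid", "gamma_grid", "n_reps",
              "theta", "threshold", "S_low", "window_periods"},
    "fdt": {"S0", "gamma", "delta"},
    "twotimescale": {"duration", "epsilon", "amplitude", "kind"},
    "compare": {"gamma", "theta", "S_low", "S_high"},
}


class ConfigError(ValueError):
    """Configuration document failed validation; message carries a key path."""


@dataclass
class RunConfig:
    protocol: str
    model_id: str
    params: dict
    signal: dict = field(default_factory=dict)
    options: dict = field(default_factory=dict)
    seed: int | None = None
    output: str = "."

    def resolved(self) -> dict:
        return {
            "protocol": self.protocol,
            "model": {"id": self.model_id, "params": dict(self.params)},
            "signal": dict(self.signal),
            "options": dict(self.options),
            "seed": self.seed,
            "output": self.output,
        }


def _reject_unknown(mapping: dict, allowed: set, path: str):
    for key in mapping:
        if key not in allowed:
            hint = get_close_matches(key, allowed, n=1)
            msg = f"unknown key {path}.{key}"
            if hint:
                msg += f" (did you mean {hint[0]!r}?)"
            raise ConfigError(msg)


def _validate(doc: dict) -> RunConfig:
    if not isinstance(doc, dict):
        raise ConfigError("configuration document must be a mapping")
    _reject_unknown(doc, _TOP_KEYS, "$")
    protocol = doc.get("protocol")
    if protocol not in PROTOCOLS:
        raise ConfigError(
            f"$.protocol must be one of {', '.join(PROTOCOLS)}, got {protocol!r}")
    model = doc.get("model")
    if not isinstance(model, dict) or "id" not in model:
        raise ConfigError("$.model must be a mapping with an 'id' key")
    _reject_unknown(model, {"id", "params"}, "$.model")
    model_id = model["id"]
    if model_id not in available_models():
        raise ConfigError(
            f"$.model.id: unknown model {model_id!r}; known: "
            f"{', '.join(available_models())}")
    params = dict(nominal_params(model_id))
    overrides = model.get("params") or {}
    known = set(params)
    for key, value in overrides.items():
        if key not in known:
            hint = get_close_matches(key, known, n=1)
            msg = f"$.model.params.{key}: unknown parameter"
            if hint:
                msg += f" (did you mean {hint[0]!r}?)"
            raise ConfigError(msg)
        params[key] = float(value)
    signal = doc.get("signal") or {}
    _reject_unknown(signal, {"S0", "delta", "gamma", "duration", "seed"},
                    "$.signal")
    options = doc.get("options") or {}
    _reject_unknown(options, _OPTION_KEYS[protocol], f"$.options[{protocol}]")
    seed = doc.get("seed")
    if seed is None and "seed" in signal:
        seed = signal["seed"]
    if protocol in _STOCHASTIC and protocol != "simulate" and seed is None:
        raise ConfigError(
            f"$.seed: protocol {protocol!r} is stochastic; an explicit integer "
            "seed is required (no wall-clock seeding)")
    return RunConfig(protocol=protocol, model_id=model_id, params=params,
                     signal=dict(signal), options=dict(options),
                     seed=None if seed is None else int(seed),
                     output=str(doc.get("output", ".")))


def load_config(path) -> RunConfig:
    """Parse and validate a YAML run configuration."""
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    return _validate(doc)


def config_from_dict(doc: dict) -> RunConfig:
    return _validate(doc)


# ---------------------------------------------------------------------------
# fixtures
# ---------------------------------------------------------------------------

def fixture_names() -> list:
    """Names of the packaged fixture configurations."""
    pkg = resources.files("fbnoise") / "fixtures"
    return sorted(p.name[:-5] for p in pkg.iterdir() if p.name.endswith(".yaml"))


def load_fixture(name: str) -> dict:
    """Raw dict of a packaged fixture configuration."""
    pkg = resources.files("fbnoise") / "fixtures"
    path = pkg / f"{name}.yaml"
    try:
        text = path.read_text()
    except FileNotFoundError:
        raise KeyError(
            f"unknown fixture {name!r}; available: {', '.join(fixture_names())}")
    return yaml.safe_load(text)


# ---------------------------------------------------------------------------
# dispatch
# ---------------------------------------------------------------------------

def _json_default(obj):
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_json(path: Path, payload: dict):
    path.write_text(json.dumps(payload, indent=2, default=_json_default) + "\n")


def run(config: RunConfig) -> int:
    """Execute a validated configuration; write artifacts; return exit code 0.

    Validation failures raise :class:`ConfigError` before anything is
    written; runtime failures propagate (the CLI maps the two cases to
    distinct exit codes).
    """
    outdir = Path(config.output)
    outdir.mkdir(parents=True, exist_ok=True)
    model = build_model(config.model_id, config.params)
    opts = config.options
    sig = config.signal
    artifacts = {}

    if config.protocol == "steady":
        ss = timescales.compute_steady_states(model, opts.get("S_low", 0.0),
                                              opts.get("S_high", 1.0))
        artifacts["steady.json"] = {
            "s_off": ss.s_off, "s_on": ss.s_on,
            "residual_off": ss.residual_off, "residual_on": ss.residual_on,
            "state_names": list(model.state_names),
        }
    elif config.protocol == "timescales":
        ts = timescales.measure_timescales(
            model, opts.get("S_low", 0.0), opts.get("S_high", 1.0),
            opts.get("gamma", sig.get("gamma", 1.0)), opts.get("theta", 0.9),
            opts.get("convention", "periods"))
        artifacts["timescales.json"] = vars(ts).copy()
    elif config.protocol == "simulate":
        duration = float(opts.get("duration", sig.get("duration", 50.0)))
        if sig.get("delta", 0.0) > 0:
            signal = PiecewiseNoiseSignal(
                S0=float(sig["S0"]), delta=float(sig["delta"]),
                gamma=float(sig.get("gamma", 1.0)), duration=duration,
                seed=int(config.seed if config.seed is not None else sig["seed"]))
        else:
            signal = ConstantSignal(float(sig.get("S0", 1.0)), duration)
        y0 = np.asarray(opts.get("initial_state", model.box_lo), dtype=float)
        traj = integrate(model, signal, y0, duration,
                         rtol=float(opts.get("rtol", 1e-8)),
                         atol=float(opts.get("atol", 1e-10)))
        traj.to_frame(model).to_csv(outdir / "trajectory.csv", index=False)
        artifacts["trajectory.meta.json"] = {
            "model": model.model_id, "duration": duration,
            "n_points": len(traj.times), "restarts": traj.n_restarts,
        }
    elif config.protocol == "noiseq":
        S_low = float(opts.get("S_low", 0.0))
        ss = timescales.compute_steady_states(model, S_low, float(sig["S0"]))
        ens = noisemetrics.ensemble_Q(
            model, float(sig["S0"]), float(sig["delta"]),
            float(sig.get("gamma", 1.0)), n_reps=int(opts.get("n_reps", 1)),
            base_seed=config.seed, initial_state=ss.s_on,
            window_periods=int(opts.get("window_periods", 1000)),
            samples_per_period=int(opts.get("samples_per_period", 20)),
            s_off_output=float(ss.s_off[model.output_index]))
        artifacts["noiseq.json"] = {
            "mean_Q": ens.mean_Q, "sem_Q": ens.sem_Q,
            "n_flipped": ens.n_flipped,
            "replicates": [vars(r).copy() for r in ens.runs],
        }
        rows = [vars(r).copy() for r in ens.runs]
        import pandas as pd
        pd.DataFrame(rows).to_csv(outdir / "noiseq_replicates.csv", index=False)
    elif config.protocol == "sweep":
        noise = experiments.NoiseSpec(
            S0=float(sig.get("S0", 1.0)), delta=float(sig.get("delta", 0.3)),
            gamma=float(sig.get("gamma", 1.0)),
            S_low=float(opts.get("S_low", 0.0)))
        n_reps = int(opts.get("n_reps", 20))
        theta = float(opts.get("theta", 0.9))
        wp = int(opts.get("window_periods", 1000))
        if "gamma_grid" in opts:
            pts = experiments.sweep_frequency(
                config.model_id, [float(g) for g in opts["gamma_grid"]], noise,
                n_reps=n_reps, base_seed=config.seed, theta=theta,
                base_params=config.params, window_periods=wp)
        else:
            param = opts["param"]
            if "grid" in opts:
                grid = [float(g) for g in opts["grid"]]
            else:
                grid = experiments.geometric_grid(
                    config.params[param], float(opts.get("fold", 2.0)),
                    int(opts.get("n_grid", 10)))
            pts = experiments.sweep_parameter(
                config.model_id, param, grid, noise, n_reps=n_reps,
                base_seed=config.seed, theta=theta, base_params=config.params,
                window_periods=wp)
        experiments.sweep_table(pts).to_csv(outdir / "sweep.csv", index=False)
        trend = experiments.trend_test(pts, float(opts.get("threshold", -0.8)))
        artifacts["trend.json"] = vars(trend).copy() | {"passed": trend.passed}
    elif config.protocol == "fdt":
        res = fdt_noise_amplification(
            config.params, float(opts.get("gamma", sig.get("gamma", 1.0))),
            float(opts.get("S0", sig.get("S0", 1.0))),
            opts.get("delta", sig.get("delta")))
        artifacts["fdt.json"] = {"Q_analytic": res.Q_analytic,
                                 "flags": res.flags,
                                 "in_regime": res.in_regime}
    elif config.protocol == "twotimescale":
        duration = float(opts.get("duration", 10.0))
        eps = float(opts.get("epsilon", 0.05))
        S0 = float(sig.get("S0", 1.0))
        delta = float(sig.get("delta", 0.3))
        fast = CenteredNoiseSignal(delta=delta, gamma=1.0 / eps,
                                   duration=duration, seed=int(config.seed))
        comp = CompositeSignal((ConstantSignal(S0, duration), fast),
                               ("slow", "fast"), duration)
        ss = timescales.compute_steady_states(model, 0.0, S0)
        full = integrate(model, comp, ss.s_on, duration)
        zero = two_timescale_zero_order(model, comp, ss.s_on, duration)
        zi = np.interp(full.times, zero.times, zero.output(model.output_index))
        err = float(np.max(np.abs(full.output(model.output_index) - zi)))
        artifacts["twotimescale.json"] = {"epsilon": eps,
                                          "sup_error": err,
                                          "duration": duration}
    elif config.protocol == "compare":
        df = experiments.compare_modules(
            gamma=float(opts.get("gamma", 1.0)),
            theta=float(opts.get("theta", 0.9)),
            S_low=float(opts.get("S_low", 0.0)),
            S_high=float(opts.get("S_high", 1.0)))
        df.to_csv(outdir / "compare.csv", index=False)
        artifacts["compare.meta.json"] = {"n_variants": len(df)}

    for name, payload in artifacts.items():
        _write_json(outdir / name, payload)
    _write_json(outdir / "resolved_config.json", config.resolved())
    return 0
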