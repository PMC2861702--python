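"""Parameter sweeps linking the signed activation time to noise amplification.

Each sweep varies one model parameter over a grid; at every grid value the
noise-free protocol yields (t_act, t_deact, T) and a replicated noisy
simulation yields (mean Q, SEM).  The headline property — Q decreases
monotonically in T — is operationalized as a Spearman rank correlation over
the sweep's (T, Q) pairs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import spearmanr

from .models import ModelSpec, build_model, nominal_params
from .noisemetrics import ensemble_Q
from .timescales import ProtocolError, compute_steady_states, measure_timescales

__all__ = [
    "SweepPoint",
    "TrendResult",
    "NoiseSpec",
    "sweep_parameter",
    "sweep_frequency",
    "trend_test",
    "compare_modules",
    "geometric_grid",
    "sweep_table",
]


@dataclass(frozen=True)
class NoiseSpec:
    """Stimulus-noise conditions shared by all points of a sweep."""

    S0: float = 1.0
    delta: float = 0.3
    gamma: float = 1.0
    S_low: float = 0.0

    def __post_init__(self):
        if self.S0 - self.delta < 0:
            raise ValueError("S0 - delta must be >= 0")


@dataclass(frozen=True)
class SweepPoint:
    param: str
    value: float
    t_act: float
    t_deact: float
    T: float
    mean_Q: float
    sem_Q: float
    n_reps: int
    n_flipped: int = 0
    failed: str = ""


@dataclass(frozen=True)
class TrendResult:
    rho: float
    n_points: int
    threshold: float

    @property
    def passed(self) -> bool:
        return self.rho <= self.threshold


def geometric_grid(center: float, fold: float, n: int) -> np.ndarray:
    """n-point geometric grid spanning ``[center/fold, center*fold]``."""
    return center * np.logspace(-np.log10(fold), np.log10(fold), n)


def _point(model: ModelSpec, noise: NoiseSpec, n_reps: int, base_seed: int,
           theta: float, gamma: float, window_periods: int,
           samples_per_period: int, param: str, value: float) -> SweepPoint:
    steady = compute_steady_states(model, noise.S_low, noise.S0)
    ts = measure_timescales(model, noise.S_low, noise.S0, gamma, theta,
                            steady=steady)
    ens = ensemble_Q(model, noise.S0, noise.delta, gamma, n_reps=n_reps,
                     base_seed=base_seed, initial_state=steady.s_on,
                     window_periods=window_periods,
                     samples_per_period=samples_per_period,
                     s_off_output=float(steady.s_off[model.output_index]))
    return SweepPoint(param=param, value=value, t_act=ts.t_act,
                      t_deact=ts.t_deact, T=ts.T, mean_Q=ens.mean_Q,
                      sem_Q=ens.sem_Q, n_reps=n_reps, n_flipped=ens.n_flipped)


def sweep_parameter(model_id: str, param: str, grid, noise: NoiseSpec,
                    n_reps: int = 20, base_seed: int = 0, theta: float = 0.9,
                    base_params: dict = None, window_periods: int = 1000,
                    samples_per_period: int = 20) -> list:
    """Vary one kinetic parameter; measure (t_act, t_deact, T, Q) per value.

    Per-point failures (no separated on/off states, integration failure) are
    recorded on the returned SweepPoint rather than raised; records are
    sorted by parameter value.  Replicate k of point j uses seed
    ``base_seed + j * n_reps + k`` so every point sees fresh noise but the
    whole table is reproducible from ``base_seed``.
    """
    base = dict(nominal_params(model_id)) if base_params is None else dict(base_params)
    points = []
    for j, value in enumerate(sorted(np.asarray(grid, dtype=float))):
        p = dict(base)
        p[param] = float(value)
        try:
            model = build_model(model_id, p)
            pt = _point(model, noise, n_reps, base_seed + j * n_reps, theta,
                        noise.gamma, window_periods, samples_per_period,
                        param, float(value))
        except (ProtocolError, RuntimeError, ValueError) as err:
            pt = SweepPoint(param=param, value=float(value), t_act=np.nan,
                            t_deact=np.nan, T=np.nan, mean_Q=np.nan,
                            sem_Q=np.nan, n_reps=n_reps, failed=str(err))
        points.append(pt)
    return points


def sweep_frequency(model_id: str, gamma_grid, noise: NoiseSpec,
                    n_reps: int = 20, base_seed: int = 0, theta: float = 0.9,
                    base_params: dict = None, window_periods: int = 1000,
                    samples_per_period: int = 20) -> list:
    """Fix the kinetics, vary the noise frequency; T is recomputed per gamma."""
    base = dict(nominal_params(model_id)) if base_params is None else dict(base_params)
    model = build_model(model_id, base)
    steady = compute_steady_states(model, noise.S_low, noise.S0)
    points = []
    for j, gamma in enumerate(sorted(np.asarray(gamma_grid, dtype=float))):
        try:
            ts = measure_timescales(model, noise.S_low, noise.S0, float(gamma),
                                    theta, steady=steady)
            ens = ensemble_Q(model, noise.S0, noise.delta, float(gamma),
                             n_reps=n_reps, base_seed=base_seed + j * n_reps,
                             initial_state=steady.s_on,
                             window_periods=window_periods,
                             samples_per_period=samples_per_period,
                             s_off_output=float(steady.s_off[model.output_index]))
            pt = SweepPoint(param="gamma", value=float(gamma), t_act=ts.t_act,
                            t_deact=ts.t_deact, T=ts.T, mean_Q=ens.mean_Q,
                            sem_Q=ens.sem_Q, n_reps=n_reps,
                            n_flipped=ens.n_flipped)
        except (ProtocolError, RuntimeError, ValueError) as err:
            pt = SweepPoint(param="gamma", value=float(gamma), t_act=np.nan,
                            t_deact=np.nan, T=np.nan, mean_Q=np.nan,
                            sem_Q=np.nan, n_reps=n_reps, failed=str(err))
        points.append(pt)
    return points


def trend_test(points, threshold: float = -0.8) -> TrendResult:
    """Spearman rank correlation between mean Q and T over a sweep.

    State-flip-flagged and failed points are excluded; ties receive average
    ranks (scipy convention).  Passing means ``rho <= threshold``.
    """
    valid = [p for p in points
             if not p.failed and np.isfinite(p.T) and np.isfinite(p.mean_Q)
             and p.n_flipped < p.n_reps]
    if len(valid) < 5:
        raise ValueError(f"need >= 5 valid sweep points, have {len(valid)}")
    T = np.array([p.T for p in valid])
    Q = np.array([p.mean_Q for p in valid])
    if np.all(Q == Q[0]) or np.all(T == T[0]):
        rho = 0.0
    else:
        rho = float(spearmanr(T, Q).statistic)
    return TrendResult(rho=rho, n_points=len(valid), threshold=threshold)


def sweep_table(points) -> pd.DataFrame:
    """Tidy one-row-per-point table of a sweep."""
    return pd.DataFrame([vars(p) for p in points])


def compare_modules(shared_params: dict = None, gamma: float = 1.0,
                    theta: float = 0.9, S_low: float = 0.0, S_high: float = 1.0,
                    variants: dict = None) -> pd.DataFrame:
    """Noise-free time scales of the loop architectures on matched parameters.

    The single-positive parameters are shared; each multi-loop variant adds
    its extra-loop block.  Default variants: fast-slow and slow-slow
    positive-positive, and fast and slow positive-negative.  Returns one row
    per architecture with (t_act, t_deact, T).
    """
    base = dict(nominal_params("single_positive")) if shared_params is None \
        else dict(shared_params)
    if variants is None:
        pp = nominal_params("positive_positive")
        pn = nominal_params("positive_negative")
        extra_pp = {k: pp[k] for k in ("k5", "k6", "k7", "b3")}
        extra_pn = {k: pn[k] for k in ("k5", "k6", "k7", "b3")}
        variants = {
            "single_positive": ("single_positive", {}),
            "positive_positive_fast_slow": (
                "positive_positive", {**extra_pp, "tau_a": 0.5}),
            "positive_positive_slow_slow": (
                "positive_positive", {**extra_pp, "tau_a": base["tau"]}),
            "positive_negative_fast": (
                "positive_negative", {**extra_pn, "tau_a": 0.5}),
            "positive_negative_slow": (
                "positive_negative", {**extra_pn, "tau_a": base["tau"]}),
        }
    rows = []
    for label, (model_id, extra) in variants.items():
        model = build_model(model_id, {**base, **extra})
        ts = measure_timescales(model, S_low, S_high, gamma, theta)
        rows.append({"variant": label, "model_id": model_id,
                     "t_act": ts.t_act, "t_deact": ts.t_deact, "T": ts.T})
    return pd.DataFrame(rows)
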