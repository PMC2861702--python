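"""Noise amplification rate Q from noisy-input simulations.

``Q = CV(output) / CV(input)`` over a stationary analysis window, with the
system prepared at its active ("on") stationary state and driven by the
piecewise-constant uniform stimulus noise.  Values below 1 mean the circuit
attenuates input fluctuations.

Estimator choices (see the methods note for rationale):

* the run starts *at* the active stationary state, so the burn-in only has
  to cover the build-up of the stationary noise response — a fixed number of
  noise periods plus several multiples of the slowest linearized relaxation
  time;
* the input CV in the denominator is computed from the realized sampled
  input on the same grid as the output, not from the theoretical
  ``delta/(sqrt(3) S0)``;
* replicates whose output abandons the active basin and spends the whole
  window near the inactive state are flagged ("state flips") and excluded
  from ensemble means rather than averaged in.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analytics import model_jacobian
from .models import ModelSpec
from .signals import PiecewiseNoiseSignal
from .simulate import integrate_ensemble, integrate_to_stationarity

__all__ = [
    "NoiseMetrics",
    "EnsembleQ",
    "coefficient_of_variation",
    "metrics_from_series",
    "noise_amplification_rate",
    "ensemble_Q",
]


def coefficient_of_variation(series, ddof: int = 1) -> float:
    """Sample standard deviation over sample mean."""
    x = np.asarray(series, dtype=float)
    if x.size == 0:
        raise ValueError("empty series")
    mean = x.mean()
    if mean == 0:
        raise ValueError("zero-mean series has no coefficient of variation")
    if x.size == 1:
        return 0.0
    return float(x.std(ddof=ddof) / abs(mean))


@dataclass(frozen=True)
class NoiseMetrics:
    cv_in: float
    cv_out: float
    Q: float
    t_burn: float
    t_end: float
    n_samples: int
    seed: int | None = None
    state_flip: bool = False


def metrics_from_series(output_series, input_series, t_burn: float = 0.0,
                        t_end: float = 0.0, seed: int | None = None,
                        state_flip: bool = False) -> NoiseMetrics:
    """Assemble Q from matched output/input sample series."""
    cv_out = coefficient_of_variation(output_series)
    cv_in = coefficient_of_variation(input_series)
    if cv_in == 0:
        raise ValueError("input series has zero variation; Q undefined")
    return NoiseMetrics(cv_in=cv_in, cv_out=cv_out, Q=cv_out / cv_in,
                        t_burn=t_burn, t_end=t_end,
                        n_samples=len(np.asarray(output_series)),
                        seed=seed, state_flip=state_flip)


def _auto_substeps(model: ModelSpec, state: np.ndarray, S0: float,
                   seg_len: float) -> int:
    rate = float(np.max(np.abs(np.linalg.eigvals(model_jacobian(model, state, S0)).real)))
    # explicit RK4 stability plus accuracy headroom
    return int(max(8, np.ceil(1.2 * rate * seg_len)))


def _burn_periods(model: ModelSpec, state: np.ndarray, S0: float,
                  gamma: float) -> int:
    lam = np.linalg.eigvals(model_jacobian(model, state, S0))
    slow = float(np.min(np.abs(lam.real)))
    t_burn = max(10.0 / gamma, 8.0 / slow if slow > 0 else 10.0 / gamma)
    return int(np.ceil(t_burn * gamma))


def _replicate_values(S0, delta, gamma, n_periods, seeds):
    rows = [
        PiecewiseNoiseSignal(S0=S0, delta=delta, gamma=gamma,
                             duration=n_periods / gamma, seed=s).values
        for s in seeds
    ]
    return np.asarray(rows)


def noise_amplification_rate(model: ModelSpec, signal: PiecewiseNoiseSignal,
                             initial_state=None, window_periods: int = 1000,
                             samples_per_period: int = 20,
                             burn_periods: int = None, substeps: int = None,
                             s_off_output: float = None) -> NoiseMetrics:
    """Single-run noise amplification rate at the active state.

    ``signal`` defines (S0, delta, gamma, seed); the run starts at the
    active stationary state under S0 (or at ``initial_state``), discards the
    burn-in, then estimates CVs over ``window_periods`` noise periods with
    ``samples_per_period`` samples each.

    If ``s_off_output`` (the inactive-state output level) is given, a run
    whose median output falls below the midpoint between the two state
    levels is flagged as a state flip.
    """
    res = ensemble_Q(model, signal.S0, signal.delta, signal.gamma, n_reps=1,
                     base_seed=signal.seed, initial_state=initial_state,
                     window_periods=window_periods,
                     samples_per_period=samples_per_period,
                     burn_periods=burn_periods, substeps=substeps,
                     s_off_output=s_off_output)
    return res.runs[0]


@dataclass(frozen=True)
class EnsembleQ:
    mean_Q: float
    sem_Q: float
    runs: tuple
    n_flipped: int = 0

    @property
    def Q_values(self):
        return [r.Q for r in self.runs if not r.state_flip]


def ensemble_Q(model: ModelSpec, S0: float, delta: float, gamma: float,
               n_reps: int, base_seed: int, initial_state=None,
               window_periods: int = 1000, samples_per_period: int = 20,
               burn_periods: int = None, substeps: int = None,
               s_off_output: float = None) -> EnsembleQ:
    """Replicated Q estimate; replicate k uses seed ``base_seed + k``.

    All replicates advance together through the fixed-step ensemble
    integrator.  Returns the arithmetic mean and standard error over
    non-flipped replicates (SEM is NaN for a single replicate).
    """
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    if delta <= 0:
        raise ValueError("noise amplitude must be positive for Q estimation")
    if initial_state is None:
        hi = np.where(np.isfinite(model.box_hi), model.box_hi, 1.0)
        initial_state, _ = integrate_to_stationarity(model, S0, hi, tol=1e-9)
    y_on = np.asarray(initial_state, dtype=float)
    seg_len = 1.0 / gamma
    if substeps is None:
        substeps = _auto_substeps(model, y_on, S0, seg_len)
    if burn_periods is None:
        burn_periods = _burn_periods(model, y_on, S0, gamma)

    seeds = [int(base_seed) + k for k in range(n_reps)]
    n_total = burn_periods + window_periods
    values = _replicate_values(S0, delta, gamma, n_total, seeds)

    # burn-in: no recording
    y = integrate_ensemble(model, values[:, :burn_periods], seg_len, y_on,
                           substeps=substeps, record=False)
    # analysis window: record samples_per_period points per period
    spp = max(1, min(samples_per_period, substeps))
    y, outputs, spp_actual = _integrate_recording(model, values[:, burn_periods:],
                                                  seg_len, y, substeps, spp)
    # matched input samples: each segment value repeated once per output sample
    in_samples = np.repeat(values[:, burn_periods:], spp_actual, axis=1)

    k_out = model.output_index
    runs = []
    n_flip = 0
    for i in range(n_reps):
        out_i = outputs[i]
        flip = False
        if s_off_output is not None:
            on_level = y_on[k_out]
            mid = 0.5 * (on_level + s_off_output)
            flip = bool(np.median(out_i) < mid)
        m = metrics_from_series(out_i, in_samples[i],
                                t_burn=burn_periods * seg_len,
                                t_end=n_total * seg_len, seed=seeds[i],
                                state_flip=flip)
        n_flip += int(flip)
        runs.append(m)

    qs = np.array([r.Q for r in runs if not r.state_flip])
    if qs.size == 0:
        raise RuntimeError("all replicates flagged as state flips; no Q estimate")
    mean_q = float(qs.mean())
    sem = float(qs.std(ddof=1) / np.sqrt(qs.size)) if qs.size > 1 else float("nan")
    return EnsembleQ(mean_Q=mean_q, sem_Q=sem, runs=tuple(runs), n_flipped=n_flip)


def _integrate_recording(model: ModelSpec, values: np.ndarray, seg_len: float,
                         y0: np.ndarray, substeps: int, samples_per_period: int):
    """RK4 sweep that records the output coordinate ``samples_per_period``
    times per segment.  Returns (final_states, outputs[n_reps, n_samples])."""
    values = np.atleast_2d(values)
    n_reps, n_seg = values.shape
    y = np.broadcast_to(np.asarray(y0, dtype=float),
                        (n_reps, model.state_dim)).copy()
    h = seg_len / substeps
    rhs = model.rhs
    lo = model.box_lo - 1e-12
    hi = model.box_hi + 1e-12
    rec_every = max(1, substeps // samples_per_period)
    spp_actual = substeps // rec_every
    k_out = model.output_index
    outputs = np.empty((n_reps, n_seg * spp_actual))
    col = 0
    for j in range(n_seg):
        s = values[:, j]
        for m in range(substeps):
            k1 = rhs(0.0, y, s)
            k2 = rhs(0.0, y + 0.5 * h * k1, s)
            k3 = rhs(0.0, y + 0.5 * h * k2, s)
            k4 = rhs(0.0, y + h * k3, s)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
            if (m + 1) % rec_every == 0 and col < outputs.shape[1]:
                outputs[:, col] = y[:, k_out]
                col += 1
        np.clip(y, lo, hi, out=y)
    if not np.all(np.isfinite(y)):
        raise RuntimeError("ensemble integration produced non-finite states")
    return y, outputs[:, :col], spp_actual
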