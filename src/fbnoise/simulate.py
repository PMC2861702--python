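"""Trajectory integration of a ModelSpec against an InputSignal.

Piecewise-constant inputs have known breakpoints, so integration proceeds
segment by segment: the solver is restarted at every input discontinuity and
each segment sees a smooth autonomous right-hand side.  A stiff-capable
method is selected automatically for the models flagged stiff (the
literature-scale circuits mix fast binding with slow recruitment); the 2-3
dimensional toy modules use an explicit Runge-Kutta method.

A separate fixed-step ensemble integrator (:func:`integrate_ensemble`)
advances many noise replicates simultaneously with classical RK4 sub-steps
inside each noise segment.  It exists for the stationary-noise statistics,
where thousands of noise periods must be traversed per replicate; its
accuracy is cross-checked against :func:`integrate` in the test suite.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .models import ModelSpec
from .signals import ConstantSignal, InputSignal

__all__ = [
    "Trajectory",
    "IntegrationError",
    "integrate",
    "integrate_to_stationarity",
    "integrate_ensemble",
]


class IntegrationError(RuntimeError):
    def __init__(self, message, segment=None):
        super().__init__(message)
        self.segment = segment


@dataclass
class Trajectory:
    """Integrated run: time grid, state matrix, sampled input, provenance."""

    times: np.ndarray
    states: np.ndarray
    inputs: np.ndarray
    model_id: str
    method: str
    rtol: float
    atol: float
    n_restarts: int = 0

    def __post_init__(self):
        if np.any(~np.isfinite(self.states)) or np.any(~np.isfinite(self.times)):
            raise IntegrationError("non-finite values in trajectory")
        if np.any(np.diff(self.times) < 0):
            raise ValueError("time grid must be nondecreasing")

    def output(self, output_index: int) -> np.ndarray:
        return self.states[:, output_index]

    def to_frame(self, model: ModelSpec = None):
        import pandas as pd

        cols = {"time": self.times}
        names = (model.state_names if model is not None
                 else [f"x{i}" for i in range(self.states.shape[1])])
        for i, name in enumerate(names):
            cols[name] = self.states[:, i]
        cols["input"] = self.inputs
        return pd.DataFrame(cols)


def _segment_edges(signal: InputSignal, duration: float) -> np.ndarray:
    bp = np.atleast_1d(np.asarray(signal.breakpoints(), dtype=float))
    bp = bp[(bp > 0) & (bp < duration)]
    return np.concatenate([[0.0], np.unique(bp), [duration]])


def integrate(model: ModelSpec, signal: InputSignal, initial_state,
              duration: float, method: str = None, rtol: float = 1e-8,
              atol: float = 1e-10, points_per_segment: int = 20,
              max_points: int = 2_000_000) -> Trajectory:
    """Integrate ``model`` under ``signal`` over ``[0, duration]``.

    The reporting grid is the union of the solver's accepted steps and a
    uniform grid of at least ``points_per_segment`` points per input segment,
    so piecewise-noise runs are sampled densely and without bias within every
    noise period.
    """
    y0 = np.asarray(initial_state, dtype=float)
    if y0.shape != (model.state_dim,):
        raise ValueError(f"initial state must have shape ({model.state_dim},)")
    if duration < 0:
        raise ValueError("duration must be >= 0")
    if duration == 0:
        s0 = float(signal(0.0))
        return Trajectory(np.array([0.0]), y0[None, :], np.array([s0]),
                          model.model_id, "none", rtol, atol)

    if method is None:
        method = "LSODA" if model.stiff else "RK45"

    edges = _segment_edges(signal, duration)
    n_seg = len(edges) - 1
    if n_seg * points_per_segment > max_points:
        points_per_segment = max(2, max_points // n_seg)

    times, states = [], []
    y = y0.copy()
    slack = 1e-9
    for i in range(n_seg):
        t0, t1 = edges[i], edges[i + 1]
        s_val = float(signal(t0))  # right-continuous: value holds on [t0, t1)
        if s_val < 0:
            raise ValueError(f"negative stimulus value {s_val} at t={t0}")
        t_eval = np.linspace(t0, t1, max(2, points_per_segment))
        sol = solve_ivp(
            lambda t, yy: model.rhs(t, yy, s_val), (t0, t1), y,
            method=method, rtol=rtol, atol=atol, t_eval=t_eval,
        )
        if not sol.success:
            raise IntegrationError(
                f"integrator failed on segment {i} [{t0:g}, {t1:g}]: {sol.message}",
                segment=i,
            )
        yseg = sol.y.T
        lo, hi = model.box_lo, model.box_hi
        if np.any(yseg < lo - 1e-6) or np.any(yseg > hi + 1e-6):
            raise IntegrationError(
                f"state left the admissible box beyond slack on segment {i}",
                segment=i,
            )
        yseg = np.clip(yseg, lo - slack, hi + slack)
        keep = slice(0, -1) if i < n_seg - 1 else slice(None)
        times.append(sol.t[keep])
        states.append(yseg[keep])
        y = yseg[-1]

    t = np.concatenate(times)
    x = np.concatenate(states)
    u = np.asarray(signal.to_samples(t), dtype=float)
    return Trajectory(t, x, u, model.model_id, method, rtol, atol,
                      n_restarts=n_seg - 1)


def _newton_polish(model: ModelSpec, y: np.ndarray, level: float, tol: float,
                   max_iter: int = 25):
    """Damped Newton refinement of a near-stationary state."""
    from .models import model_jacobian

    y = y.copy()
    res = float(np.max(np.abs(model.rhs(0.0, y, level))))
    for _ in range(max_iter):
        if res < tol:
            break
        try:
            step = np.linalg.solve(model_jacobian(model, y, level),
                                   model.rhs(0.0, y, level))
        except np.linalg.LinAlgError:
            break
        lam = 1.0
        improved = False
        for _damp in range(8):
            cand = np.clip(y - lam * step, model.box_lo, model.box_hi)
            r = float(np.max(np.abs(model.rhs(0.0, cand, level))))
            if r < res:
                y, res, improved = cand, r, True
                break
            lam *= 0.5
        if not improved:
            break
    return y, res


def integrate_to_stationarity(model: ModelSpec, constant_level: float,
                              initial_state, tol: float = 1e-9,
                              max_time: float = 1e5, chunk: float = 50.0):
    """Integrate under a constant input until ``||RHS||_inf < tol``.

    Relaxation chunks carry the state into the attracting basin; once the
    residual is small (or stalls at the integrator's error floor) a damped
    Newton polish finishes the job.  Returns ``(state, converged)``;
    non-convergence within ``max_time`` is a flagged result, not an
    exception.
    """
    if tol <= 0:
        raise ValueError("tol must be positive")
    y = np.asarray(initial_state, dtype=float)
    elapsed = 0.0
    sig = ConstantSignal(constant_level, duration=np.inf)
    while elapsed < max_time:
        res = float(np.max(np.abs(model.rhs(0.0, y, constant_level))))
        if res < tol:
            return y, True
        if res < 1e-3:
            y_p, res_p = _newton_polish(model, y, constant_level, tol)
            if res_p < tol:
                return y_p, True
            y = y_p
        step = min(chunk, max_time - elapsed)
        traj = integrate(model, sig, y, step, rtol=1e-10, atol=1e-12,
                         points_per_segment=2)
        y_new = traj.states[-1]
        stalled = bool(np.max(np.abs(y_new - y)) < 1e-13)
        y = y_new
        elapsed += step
        if stalled:
            break
    y, res = _newton_polish(model, y, constant_level, tol)
    return y, bool(res < tol)


def integrate_ensemble(model: ModelSpec, values: np.ndarray, seg_len: float,
                       initial_state: np.ndarray, substeps: int = 16,
                       record: bool = True, thin: int = 1):
    """Advance an ensemble through piecewise-constant input segments.

    ``values`` has shape ``(n_reps, n_segments)`` — one piecewise-constant
    input realization per replicate.  Classical RK4 with ``substeps`` equal
    sub-steps per segment; states are clipped to the admissible box after
    each segment (guards round-off at the box boundary, slack 1e-12).

    Returns ``(t_grid, states)`` where states has shape
    ``(n_recorded, n_reps, dim)`` holding the state at the *end* of each
    recorded segment, or just the final state array if ``record`` is False.
    """
    values = np.atleast_2d(np.asarray(values, dtype=float))
    n_reps, n_seg = values.shape
    y = np.broadcast_to(np.asarray(initial_state, dtype=float),
                        (n_reps, model.state_dim)).copy()
    h = seg_len / substeps
    rhs = model.rhs
    lo = model.box_lo - 1e-12
    hi = model.box_hi + 1e-12
    out = []
    t_rec = []
    for j in range(n_seg):
        s = values[:, j]  # shape (n_reps,): broadcasts against per-state slices
        for _ in range(substeps):
            k1 = _rhs_vec(rhs, y, s)
            k2 = _rhs_vec(rhs, y + 0.5 * h * k1, s)
            k3 = _rhs_vec(rhs, y + 0.5 * h * k2, s)
            k4 = _rhs_vec(rhs, y + h * k3, s)
            y = y + (h / 6.0) * (k1 + 2.0 * k2 + 2.0 * k3 + k4)
        np.clip(y, lo, hi, out=y)
        if record and (j % thin == thin - 1):
            out.append(y.copy())
            t_rec.append((j + 1) * seg_len)
    if not np.all(np.isfinite(y)):
        raise IntegrationError("ensemble integration produced non-finite states")
    if record:
        return np.asarray(t_rec), np.asarray(out)
    return y


def _rhs_vec(rhs, y, s):
    # models' rhs functions broadcast the stimulus against the replicate axis
    return rhs(0.0, y, s)
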