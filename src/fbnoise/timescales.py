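"""Activation / deactivation time scales and the signed activation time.

Both time scales are properties of the *noise-free* system.  With the
stimulus held at its low (high) level the system settles into an inactive
(active) stationary state; the activation time ``t_act`` is the time the
output needs, starting from the inactive state under the high stimulus, to
traverse a fraction ``theta`` (default 0.9) of the gap between the two
stationary output levels.  The deactivation time ``t_deact`` mirrors this
for the high-to-low switch.

The signed activation time is ``T = gamma * (t_deact - t_act)``: the
difference of the two time scales measured in periods of the input noise
(``gamma`` is the noise frequency).  It is the package's central diagnostic:
noise amplification decreases as T grows.  Because "normalized by the noise
frequency" admits two readings, the normalization is pluggable
(``convention="periods"`` multiplies by gamma; ``convention="per_frequency"``
divides).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.integrate import solve_ivp
from scipy.optimize import brentq, root

from .models import ModelSpec
from .simulate import integrate_to_stationarity

__all__ = [
    "SteadyStates",
    "TimescaleResult",
    "ProtocolError",
    "compute_steady_states",
    "measure_activation_time",
    "measure_deactivation_time",
    "signed_activation_time",
    "measure_timescales",
]


class ProtocolError(RuntimeError):
    """The on/off protocol is not realizable (no separated stationary states)."""


@dataclass(frozen=True)
class SteadyStates:
    s_off: np.ndarray
    s_on: np.ndarray
    residual_off: float
    residual_on: float
    S_low: float
    S_high: float
    output_index: int

    @property
    def gap(self) -> float:
        return float(self.s_on[self.output_index] - self.s_off[self.output_index])


@dataclass(frozen=True)
class TimescaleResult:
    t_act: float
    t_deact: float
    theta: float
    gamma: float
    T: float
    convention: str = "periods"


def _refine_fixed_point(model: ModelSpec, level: float, guess: np.ndarray,
                        residual_tol: float = 1e-10) -> tuple:
    sol = root(lambda y: model.rhs(0.0, y, level), guess, method="hybr",
               tol=1e-13)
    y = sol.x
    res = float(np.max(np.abs(model.rhs(0.0, y, level))))
    if not sol.success or res > residual_tol or np.any(y < model.box_lo - 1e-8) \
            or np.any(y > model.box_hi + 1e-8):
        # fall back to the relaxation terminus itself
        y, _ = integrate_to_stationarity(model, level, guess, tol=residual_tol,
                                         max_time=2e5)
        res = float(np.max(np.abs(model.rhs(0.0, y, level))))
    return np.clip(y, model.box_lo, model.box_hi), res


def compute_steady_states(model: ModelSpec, S_low: float, S_high: float,
                          initial_state=None, residual_tol: float = 1e-10
                          ) -> SteadyStates:
    """Inactive and active stationary states under the two stimulus levels.

    Seeds damped root-finding from relaxation termini: the off state is
    reached from ``initial_state`` (default: the admissible-box floor) under
    ``S_low``; the on state from the off state under ``S_high`` — the same
    path a step protocol follows, so in a bistable window the physically
    selected branches are found.
    """
    if not S_low < S_high:
        raise ValueError("need S_low < S_high")
    y0 = (np.asarray(initial_state, dtype=float) if initial_state is not None
          else model.box_lo.copy())
    off_guess, _ = integrate_to_stationarity(model, S_low, y0, tol=1e-10)
    s_off, r_off = _refine_fixed_point(model, S_low, off_guess, residual_tol)
    on_guess, _ = integrate_to_stationarity(model, S_high, s_off, tol=1e-10)
    s_on, r_on = _refine_fixed_point(model, S_high, on_guess, residual_tol)
    k = model.output_index
    if not s_on[k] > s_off[k]:
        raise ProtocolError(
            f"active output {s_on[k]:.4g} does not exceed inactive output "
            f"{s_off[k]:.4g}; on/off protocol rejected"
        )
    return SteadyStates(s_off, s_on, r_off, r_on, S_low, S_high, k)


def _crossing_time(model: ModelSpec, start: np.ndarray, level: float,
                   target: float, rising: bool, horizon: float) -> float:
    """First time the output crosses ``target`` under constant stimulus."""
    k = model.output_index
    sign = 1.0 if rising else -1.0
    if sign * (start[k] - target) >= 0:
        return 0.0

    def event(t, y):
        return y[k] - target

    event.terminal = True
    event.direction = sign
    method = "LSODA" if model.stiff else "RK45"
    sol = solve_ivp(lambda t, y: model.rhs(t, y, level), (0.0, horizon), start,
                    method=method, rtol=1e-10, atol=1e-12, events=event,
                    dense_output=True)
    if not sol.success:
        raise RuntimeError(f"integration failed while locating crossing: {sol.message}")
    if len(sol.t_events[0]) == 0:
        raise RuntimeError(
            f"output did not cross {target:.4g} within horizon {horizon:g}"
        )
    t_ev = float(sol.t_events[0][0])
    # polish with brentq on the dense output around the event
    lo = max(0.0, t_ev - 1e-6 * max(t_ev, 1.0))
    hi = min(sol.t[-1], t_ev + 1e-6 * max(t_ev, 1.0))
    f = lambda t: sol.sol(t)[k] - target
    try:
        if f(lo) * f(hi) < 0:
            t_ev = brentq(f, lo, hi, xtol=1e-12, rtol=1e-14)
    except ValueError:
        pass
    return float(t_ev)


def measure_activation_time(model: ModelSpec, s_off: np.ndarray, S_high: float,
                            theta: float = 0.9, s_on: np.ndarray = None,
                            horizon: float = 1e5, start=None) -> float:
    """Time to cover fraction ``theta`` of the output gap, off -> on.

    The threshold is defined by the (s_off, s_on) pair; integration starts
    from ``start`` (default: the inactive state itself).  A start already
    past the threshold yields 0.
    """
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie in (0, 1)")
    if s_on is None:
        s_on, _ = integrate_to_stationarity(model, S_high, s_off, tol=1e-10)
    k = model.output_index
    target = s_off[k] + theta * (s_on[k] - s_off[k])
    y0 = np.asarray(s_off if start is None else start, dtype=float)
    return _crossing_time(model, y0, S_high, target, rising=True,
                          horizon=horizon)


def measure_deactivation_time(model: ModelSpec, s_on: np.ndarray, S_low: float,
                              theta: float = 0.9, s_off: np.ndarray = None,
                              horizon: float = 1e5, start=None) -> float:
    """Time to cover fraction ``theta`` of the output gap, on -> off."""
    if not 0.0 < theta < 1.0:
        raise ValueError("theta must lie in (0, 1)")
    if s_off is None:
        s_off, _ = integrate_to_stationarity(model, S_low, s_on, tol=1e-10)
    k = model.output_index
    target = s_on[k] - theta * (s_on[k] - s_off[k])
    y0 = np.asarray(s_on if start is None else start, dtype=float)
    return _crossing_time(model, y0, S_low, target, rising=False,
                          horizon=horizon)


def signed_activation_time(t_act: float, t_deact: float, gamma: float,
                           convention: str = "periods") -> float:
    """``T = gamma * (t_deact - t_act)`` (default) or ``(t_deact - t_act) / gamma``."""
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    diff = t_deact - t_act
    if convention == "periods":
        return gamma * diff
    if convention == "per_frequency":
        return diff / gamma
    raise ValueError(f"unknown normalization convention {convention!r}")


def measure_timescales(model: ModelSpec, S_low: float, S_high: float,
                       gamma: float, theta: float = 0.9,
                       convention: str = "periods",
                       steady: SteadyStates = None) -> TimescaleResult:
    """Full noise-free protocol: steady states, both time scales, and T."""
    if steady is None:
        steady = compute_steady_states(model, S_low, S_high)
    t_act = measure_activation_time(model, steady.s_off, S_high, theta,
                                    s_on=steady.s_on)
    t_deact = measure_deactivation_time(model, steady.s_on, S_low, theta,
                                        s_off=steady.s_off)
    T = signed_activation_time(t_act, t_deact, gamma, convention)
    return TimescaleResult(t_act, t_deact, theta, gamma, T, convention)
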