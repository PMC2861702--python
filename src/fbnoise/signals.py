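"""Stimulus signals: deterministic protocols and piecewise-constant input noise.

The noisy stimulus is the extrinsic-noise model used throughout the package:
time is divided into sub-intervals of length ``1/gamma`` (``gamma`` is the
noise frequency) and on each sub-interval the signal takes an independent
draw from the uniform distribution on ``[S0 - delta, S0 + delta]``.  Its
coefficient of variation is therefore ``delta / (sqrt(3) * S0)``.

All signals are right-continuous with right-open segments ``[k/gamma,
(k+1)/gamma)``, so an ODE integrator can be restarted at the (known)
breakpoints and every integration segment sees a smooth right-hand side.
Noisy signals are pure functions of their construction arguments and an
integer seed: the same ``(spec, seed)`` pair always yields bitwise-identical
sample values.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

__all__ = [
    "InputSignal",
    "ConstantSignal",
    "StepSignal",
    "PiecewiseNoiseSignal",
    "SquareWaveSignal",
    "CenteredNoiseSignal",
    "CompositeSignal",
    "make_noisy_signal",
    "make_step_signal",
    "make_pulse_signal",
    "decompose_fast_slow",
]


class InputSignal:
    """Base class: a stimulus evaluable at any time in ``[0, duration]``."""

    duration: float

    def __call__(self, t):
        raise NotImplementedError

    def breakpoints(self) -> np.ndarray:
        """Interior discontinuity times, sorted, within (0, duration)."""
        return np.empty(0)

    def to_samples(self, times: Sequence[float]) -> np.ndarray:
        return np.asarray(self(np.asarray(times, dtype=float)))

    def to_csv(self, path, times: Sequence[float]):
        """Write (time, value) samples of the signal as two-column CSV."""
        import pandas as pd

        times = np.asarray(times, dtype=float)
        pd.DataFrame({"time": times, "value": self.to_samples(times)}) \
            .to_csv(path, index=False)


@dataclass(frozen=True)
class ConstantSignal(InputSignal):
    level: float
    duration: float = np.inf

    def __post_init__(self):
        if self.level < 0:
            raise ValueError("signal level must be nonnegative")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        return np.broadcast_to(np.float64(self.level), t.shape).copy() if t.ndim else float(self.level)


@dataclass(frozen=True)
class StepSignal(InputSignal):
    """Right-continuous step: ``level_before`` on [0, t_switch), ``level_after`` after."""

    level_before: float
    level_after: float
    t_switch: float
    duration: float

    def __post_init__(self):
        if self.level_before < 0 or self.level_after < 0:
            raise ValueError("signal levels must be nonnegative")
        if not (0.0 < self.t_switch < self.duration):
            raise ValueError("t_switch must lie strictly inside (0, duration)")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.where(t < self.t_switch, self.level_before, self.level_after)
        return float(out) if out.ndim == 0 else out

    def breakpoints(self):
        return np.array([self.t_switch])


@dataclass(frozen=True)
class PiecewiseNoiseSignal(InputSignal):
    """Piecewise-constant uniform noise around baseline ``S0``.

    Segment k covers ``[k/gamma, (k+1)/gamma)`` and holds one draw from
    ``U[S0 - delta, S0 + delta]``.  Construction fails if ``S0 - delta < 0``:
    negative stimulus values are rejected, never clipped.
    """

    S0: float
    delta: float
    gamma: float
    duration: float
    seed: int
    values: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.delta < 0:
            raise ValueError("noise amplitude delta must be >= 0")
        if self.S0 - self.delta < 0:
            raise ValueError(
                f"S0 - delta = {self.S0 - self.delta:g} < 0: noisy signal would go negative"
            )
        if self.gamma <= 0 or self.duration <= 0:
            raise ValueError("gamma and duration must be positive")
        n_seg = int(np.ceil(self.duration * self.gamma))
        rng = np.random.default_rng(int(self.seed))
        vals = rng.uniform(self.S0 - self.delta, self.S0 + self.delta, size=n_seg)
        object.__setattr__(self, "values", vals)

    @property
    def segment_length(self) -> float:
        return 1.0 / self.gamma

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.clip((t * self.gamma).astype(int), 0, len(self.values) - 1)
        out = self.values[idx]
        return float(out) if out.ndim == 0 else out

    def breakpoints(self):
        n_seg = len(self.values)
        bp = np.arange(1, n_seg) / self.gamma
        return bp[bp < self.duration]


@dataclass(frozen=True)
class SquareWaveSignal(InputSignal):
    """Zero-mean square wave: ``+amplitude`` on the first half of each period.

    A *fluctuation component* for composite inputs: it takes negative values,
    so it is only admissible summed with a baseline that keeps the total
    stimulus nonnegative.
    """

    amplitude: float
    period: float
    duration: float

    def __post_init__(self):
        if self.period <= 0:
            raise ValueError("period must be positive")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        phase = np.mod(t / self.period, 1.0)
        out = np.where(phase < 0.5, self.amplitude, -self.amplitude)
        return float(out) if out.ndim == 0 else out

    def breakpoints(self):
        half = 0.5 * self.period
        n = int(np.floor(self.duration / half))
        bp = half * np.arange(1, n + 1)
        return bp[bp < self.duration]


@dataclass(frozen=True)
class CenteredNoiseSignal(InputSignal):
    """Zero-mean piecewise-constant uniform noise on ``[-delta, +delta]``.

    The fluctuation part of the noisy stimulus: segment k of length
    ``1/gamma`` holds one draw from ``U[-delta, delta]``.  Combine with a
    constant baseline ``S0 >= delta`` in a :class:`CompositeSignal` to
    recover the standard noisy stimulus exactly (same seed convention).
    """

    delta: float
    gamma: float
    duration: float
    seed: int
    values: np.ndarray = field(init=False, repr=False, compare=False)

    def __post_init__(self):
        if self.delta < 0 or self.gamma <= 0 or self.duration <= 0:
            raise ValueError("need delta >= 0, gamma > 0, duration > 0")
        n_seg = int(np.ceil(self.duration * self.gamma))
        rng = np.random.default_rng(int(self.seed))
        vals = rng.uniform(-self.delta, self.delta, size=n_seg)
        object.__setattr__(self, "values", vals)

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        idx = np.clip((t * self.gamma).astype(int), 0, len(self.values) - 1)
        out = self.values[idx]
        return float(out) if out.ndim == 0 else out

    def breakpoints(self):
        n_seg = len(self.values)
        bp = np.arange(1, n_seg) / self.gamma
        return bp[bp < self.duration]


@dataclass(frozen=True)
class CompositeSignal(InputSignal):
    """Pointwise sum of component signals, each tagged ``fast`` or ``slow``.

    The tags drive the two-time-scale machinery: the zero-order slow equation
    is fed only the slow-tagged part.  No scale inference is performed —
    untagged composites are rejected.
    """

    components: tuple
    tags: tuple
    duration: float

    def __post_init__(self):
        if len(self.components) != len(self.tags) or not self.components:
            raise ValueError("components and tags must be nonempty and aligned")
        for tag in self.tags:
            if tag not in ("fast", "slow"):
                raise ValueError(f"component tag must be 'fast' or 'slow', got {tag!r}")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = sum(np.asarray(c(t)) for c in self.components)
        return float(out) if np.ndim(out) == 0 else out

    def breakpoints(self):
        bps = np.concatenate([np.atleast_1d(c.breakpoints()) for c in self.components])
        return np.unique(bps[(bps > 0) & (bps < self.duration)])

    def part(self, tag: str) -> InputSignal:
        comps = tuple(c for c, tg in zip(self.components, self.tags) if tg == tag)
        if not comps:
            return ConstantSignal(0.0, self.duration)
        if len(comps) == 1:
            return comps[0]
        return CompositeSignal(comps, tuple(tag for _ in comps), self.duration)


def make_noisy_signal(S0: float, delta: float, gamma: float, duration: float,
                      seed: int) -> PiecewiseNoiseSignal:
    """Piecewise-constant uniform noise: iid U[S0-delta, S0+delta] per 1/gamma segment."""
    return PiecewiseNoiseSignal(S0=S0, delta=delta, gamma=gamma, duration=duration, seed=seed)


def make_step_signal(level_before: float, level_after: float, t_switch: float,
                     duration: float) -> InputSignal:
    if level_before == level_after:
        return ConstantSignal(level_before, duration)
    return StepSignal(level_before, level_after, t_switch, duration)


@dataclass(frozen=True)
class PulseSignal(InputSignal):
    """Two-step pulse: ``low`` / ``high`` / ``low`` with right-continuous switches."""

    low: float
    high: float
    t_on: float
    t_off: float
    duration: float

    def __post_init__(self):
        if self.low < 0 or self.high < 0:
            raise ValueError("signal levels must be nonnegative")
        if not (0.0 < self.t_on < self.t_off < self.duration):
            raise ValueError("need 0 < t_on < t_off < duration")

    def __call__(self, t):
        t = np.asarray(t, dtype=float)
        out = np.where((t >= self.t_on) & (t < self.t_off), self.high, self.low)
        return float(out) if out.ndim == 0 else out

    def breakpoints(self):
        return np.array([self.t_on, self.t_off])


def make_pulse_signal(low: float, high: float, t_on: float, t_off: float,
                      duration: float) -> PulseSignal:
    return PulseSignal(low, high, t_on, t_off, duration)


def decompose_fast_slow(signal: InputSignal):
    """Split a tagged composite into its (slow, fast) parts.

    The parts sum back to the original pointwise (exactly, up to floating
    point addition order).  Signals that are not tagged composites cannot be
    decomposed — the time scale of a component is declared, never inferred.
    """
    if not isinstance(signal, CompositeSignal):
        raise TypeError("decompose_fast_slow requires a tagged CompositeSignal")
    return signal.part("slow"), signal.part("fast")
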