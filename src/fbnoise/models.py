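"""Feedback-circuit ODE modules and their parameter schemas.

Every model is a small input-output ODE system: an external stimulus ``S(t)``
drives one or more feedback loop species, which in turn set the level of an
output species.  The toy modules use normalized concentrations (each state in
``[0, 1]`` represents the active fraction of a species):

``single_positive`` (states ``C`` output, ``B`` loop)::

    dC/dt = (k1*B + b1)*(1 - C) - k2*C
    tau * dB/dt = (k3*S(t)*C + b2)*(1 - B) - k4*B

The loop species ``B`` is activated by the stimulus *with the help of* the
output (the ``S*C`` product is the positive feedback), deactivated at rate
``k4``, and has a small stimulus-independent basal activation ``b2``.  The
output is activated by the loop at association constant ``k1``, with basal
activation ``b1`` and deactivation rate ``k2``.  ``tau`` is the loop time
scale: large ``tau`` means a slow loop.  With ``k3*S`` large the stationary
response is switch-like: a low stimulus holds the output near a small basal
level, a high stimulus near saturation.

``positive_positive`` adds a second activating loop ``A`` (association ``k5``
into the output, stimulus coupling ``k6``, deactivation ``k7``, basal ``b3``,
time scale ``tau_a``); the two loops enter the output equation symmetrically.
``positive_negative`` keeps loop ``A`` but lets it *deactivate* the output
(term ``- k5*A*C``) instead of activating it.

Hill variants replace the mass-action association terms with saturating Hill
functions ``x^n / (K^n + x^n)``.

Two literature-scale circuits are included: a non-spatial yeast pheromone
polarization pathway (receptor / G-protein cycle / Cdc24-Bem1 positive loop /
Cla4 negative loop, output active Cdc42) with conservation pools, and a
five-variable polymyxin-B resistance connector circuit (input phospho-PhoP,
output pbgP mRNA) in which a connector protein protects the phosphorylated
response regulator from dephosphorylation.

Custom circuits register through :func:`register_model` using the same
:class:`ModelSpec` contract.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from difflib import get_close_matches
from typing import Callable, Mapping

import numpy as np

__all__ = [
    "SchemaError",
    "ConservationError",
    "ConservedPool",
    "ModelSpec",
    "build_model",
    "register_model",
    "available_models",
    "nominal_params",
    "closed_form_no_feedback",
    "hill",
]


class SchemaError(ValueError):
    """Parameter set does not satisfy the model's schema."""


class ConservationError(ValueError):
    """A conservation pool produced a negative derived concentration."""


# parameter kinds: value constraints applied at validation time
_KINDS = {
    "rate": lambda v: v >= 0,          # kinetic / association / basal constants
    "timescale": lambda v: v > 0,      # loop time scales (tau's)
    "hill": lambda v: v >= 1,          # Hill coefficients
    "halfsat": lambda v: v > 0,        # Hill half-saturation constants
    "conc": lambda v: v > 0,           # totals, scale factors
}

_KIND_MSG = {
    "rate": ">= 0",
    "timescale": "> 0",
    "hill": ">= 1 (Hill coefficient)",
    "halfsat": "> 0 (half-saturation)",
    "conc": "> 0 (total/scale)",
}


def validate_params(schema: Mapping[str, str], params: Mapping[str, float]) -> dict:
    """Check ``params`` against ``schema`` (name -> kind); return a plain dict.

    Missing or unknown keys raise :class:`SchemaError`; unknown keys name
    their closest schema match to make config typos easy to fix.
    """
    missing = sorted(set(schema) - set(params))
    if missing:
        raise SchemaError(f"missing parameter(s): {', '.join(missing)}")
    unknown = sorted(set(params) - set(schema))
    if unknown:
        hints = []
        for key in unknown:
            match = get_close_matches(key, schema.keys(), n=1)
            hints.append(f"{key!r}" + (f" (did you mean {match[0]!r}?)" if match else ""))
        raise SchemaError(f"unknown parameter(s): {', '.join(hints)}")
    out = {}
    for name, kind in schema.items():
        value = float(params[name])
        if not np.isfinite(value):
            raise SchemaError(f"parameter {name!r} must be finite, got {value}")
        if not _KINDS[kind](value):
            raise SchemaError(f"parameter {name!r} must be {_KIND_MSG[kind]}, got {value}")
        out[name] = value
    return out


def fd_jacobian(model: "ModelSpec", y: np.ndarray, s: float) -> np.ndarray:
    """Central finite-difference Jacobian, step ``max(1e-6, 1e-6*|x_j|)``."""
    y = np.asarray(y, dtype=float)
    n = y.size
    J = np.empty((n, n))
    for j in range(n):
        h = max(1e-6, 1e-6 * abs(y[j]))
        yp = y.copy()
        ym = y.copy()
        yp[j] += h
        ym[j] -= h
        J[:, j] = (model.rhs(0.0, yp, s) - model.rhs(0.0, ym, s)) / (2.0 * h)
    return J


def model_jacobian(model: "ModelSpec", y: np.ndarray, s: float) -> np.ndarray:
    """Analytic Jacobian where the model ships one, finite differences otherwise."""
    if model.jacobian is not None:
        return np.asarray(model.jacobian(np.asarray(y, dtype=float), s))
    return fd_jacobian(model, y, s)


def hill(x, K, n):
    """Saturating Hill function ``x^n / (K^n + x^n)``, vectorized, 0 at 0."""
    xn = np.asarray(x, dtype=float) ** n
    return xn / (K**n + xn)


@dataclass(frozen=True)
class ConservedPool:
    """Mass-conservation rule closing one derived species.

    derived = (total - sum_i weight_i * state_i) — the weights carry any
    membrane-to-cytoplasm (surface-area / volume) scaling.  The derived
    concentration must stay nonnegative along admissible trajectories.
    """

    name: str
    members: tuple
    weights: tuple
    total: float

    def derived(self, state: np.ndarray, index: Mapping[str, int]):
        acc = np.asarray(state[..., 0]) * 0.0 + self.total
        for m, w in zip(self.members, self.weights):
            acc = acc - w * state[..., index[m]]
        return acc


@dataclass(frozen=True)
class ModelSpec:
    """A named ODE module: right-hand side plus bookkeeping.

    ``rhs(t, y, s)`` accepts states of shape ``(dim,)`` or ``(n, dim)``
    (replicate-vectorized) and a scalar stimulus value ``s``; it returns
    derivatives of the same shape.  The stimulus always enters by value, so
    deterministic and noisy inputs share one code path.
    """

    model_id: str
    state_names: tuple
    output_index: int
    params: dict
    rhs: Callable = field(compare=False)
    box_lo: np.ndarray = field(compare=False)
    box_hi: np.ndarray = field(compare=False)
    pools: tuple = ()
    jacobian: Callable | None = field(default=None, compare=False)  # d rhs/d y at (y, s)
    stimulus_jac: Callable | None = field(default=None, compare=False)  # d rhs/d s at (y, s)
    stiff: bool = False

    @property
    def state_dim(self) -> int:
        return len(self.state_names)

    @property
    def output_name(self) -> str:
        return self.state_names[self.output_index]

    def __post_init__(self):
        if len(set(self.state_names)) != len(self.state_names):
            raise ValueError("state names must be unique")
        if not (0 <= self.output_index < self.state_dim):
            raise ValueError("output index out of range")

    def __call__(self, t, y, s):
        y = np.asarray(y, dtype=float)
        if np.isnan(y).any():
            raise ValueError("NaN in state passed to model RHS")
        if s < 0 or np.isnan(s):
            raise ValueError(f"stimulus value must be nonnegative, got {s}")
        return self.rhs(t, y, s)

    def index(self) -> dict:
        return {name: i for i, name in enumerate(self.state_names)}

    def derived_species(self, state, check: bool = True, tol: float = 1e-9) -> dict:
        """Evaluate every conservation pool; optionally verify nonnegativity."""
        idx = self.index()
        out = {}
        for pool in self.pools:
            val = pool.derived(np.asarray(state, dtype=float), idx)
            if check and np.any(val < -tol):
                raise ConservationError(
                    f"pool {pool.name!r} yields negative derived concentration "
                    f"(min {np.min(val):.3g})"
                )
            out[pool.name] = val
        return out

    def clip_to_box(self, y: np.ndarray, slack: float = 0.0) -> np.ndarray:
        return np.clip(y, self.box_lo - slack, self.box_hi + slack)


# ---------------------------------------------------------------------------
# toy feedback modules (normalized concentrations)
# ---------------------------------------------------------------------------

SINGLE_POSITIVE_SCHEMA = {
    "k1": "rate",   # B -> C association constant
    "k2": "rate",   # output deactivation rate
    "k3": "rate",   # stimulus(+output) -> B association constant
    "k4": "rate",   # loop deactivation rate
    "b1": "rate",   # output basal activation
    "b2": "rate",   # loop basal activation
    "tau": "timescale",  # loop time scale
}

SINGLE_POSITIVE_NOMINAL = {
    "k1": 10.0, "k2": 1.0, "k3": 10.0, "k4": 1.0,
    "b1": 0.01, "b2": 0.001, "tau": 5.0,
}


def _build_single_positive(params: Mapping[str, float]) -> ModelSpec:
    p = validate_params(SINGLE_POSITIVE_SCHEMA, params)
    k1, k2, k3, k4, b1, b2, tau = (p[k] for k in ("k1", "k2", "k3", "k4", "b1", "b2", "tau"))

    def rhs(t, y, s):
        C = y[..., 0]
        B = y[..., 1]
        dC = (k1 * B + b1) * (1.0 - C) - k2 * C
        dB = ((k3 * s * C + b2) * (1.0 - B) - k4 * B) / tau
        return np.stack([dC, dB], axis=-1)

    def jac(y, s):
        C, B = y[0], y[1]
        return np.array([
            [-(k1 * B + b1) - k2, k1 * (1.0 - C)],
            [k3 * s * (1.0 - B) / tau, -(k3 * s * C + b2 + k4) / tau],
        ])

    def sjac(y, s):
        C, B = y[0], y[1]
        return np.array([0.0, k3 * C * (1.0 - B) / tau])

    return ModelSpec(
        model_id="single_positive",
        state_names=("C", "B"),
        output_index=0,
        params=p,
        rhs=rhs,
        jacobian=jac,
        stimulus_jac=sjac,
        box_lo=np.zeros(2),
        box_hi=np.ones(2),
    )


_PP_EXTRA = {
    "k5": "rate",   # A -> C association constant (second loop)
    "k6": "rate",   # stimulus(+output) -> A association constant
    "k7": "rate",   # second-loop deactivation rate
    "b3": "rate",   # second-loop basal activation
    "tau_a": "timescale",  # second-loop time scale
}

POSITIVE_POSITIVE_SCHEMA = {**SINGLE_POSITIVE_SCHEMA, **_PP_EXTRA}

# matched to the single-positive nominal set; tau_a = 0.5 is the fast-slow
# regime, set tau_a = tau for slow-slow
POSITIVE_POSITIVE_NOMINAL = {
    **SINGLE_POSITIVE_NOMINAL,
    "k5": 10.0, "k6": 10.0, "k7": 1.0, "b3": 0.001, "tau_a": 0.5,
}


def _build_positive_positive(params: Mapping[str, float]) -> ModelSpec:
    p = validate_params(POSITIVE_POSITIVE_SCHEMA, params)
    k1, k2, k3, k4, b1, b2, tau = (p[k] for k in ("k1", "k2", "k3", "k4", "b1", "b2", "tau"))
    k5, k6, k7, b3, tau_a = (p[k] for k in ("k5", "k6", "k7", "b3", "tau_a"))

    def rhs(t, y, s):
        C = y[..., 0]
        B = y[..., 1]
        A = y[..., 2]
        dC = (k1 * B + k5 * A + b1) * (1.0 - C) - k2 * C
        dB = ((k3 * s * C + b2) * (1.0 - B) - k4 * B) / tau
        dA = ((k6 * s * C + b3) * (1.0 - A) - k7 * A) / tau_a
        return np.stack([dC, dB, dA], axis=-1)

    def jac(y, s):
        C, B, A = y[0], y[1], y[2]
        return np.array([
            [-(k1 * B + k5 * A + b1) - k2, k1 * (1.0 - C), k5 * (1.0 - C)],
            [k3 * s * (1.0 - B) / tau, -(k3 * s * C + b2 + k4) / tau, 0.0],
            [k6 * s * (1.0 - A) / tau_a, 0.0, -(k6 * s * C + b3 + k7) / tau_a],
        ])

    def sjac(y, s):
        C, B, A = y[0], y[1], y[2]
        return np.array([
            0.0,
            k3 * C * (1.0 - B) / tau,
            k6 * C * (1.0 - A) / tau_a,
        ])

    return ModelSpec(
        model_id="positive_positive",
        state_names=("C", "B", "A"),
        output_index=0,
        params=p,
        rhs=rhs,
        jacobian=jac,
        stimulus_jac=sjac,
        box_lo=np.zeros(3),
        box_hi=np.ones(3),
    )


POSITIVE_NEGATIVE_SCHEMA = dict(POSITIVE_POSITIVE_SCHEMA)

# slow negative loop (tau_a = tau): the regime in which the A-loop couplings
# move the signed activation time appreciably
POSITIVE_NEGATIVE_NOMINAL = {
    **SINGLE_POSITIVE_NOMINAL,
    "k5": 2.0, "k6": 10.0, "k7": 1.0, "b3": 0.001, "tau_a": 5.0,
}


def _build_positive_negative(params: Mapping[str, float]) -> ModelSpec:
    p = validate_params(POSITIVE_NEGATIVE_SCHEMA, params)
    k1, k2, k3, k4, b1, b2, tau = (p[k] for k in ("k1", "k2", "k3", "k4", "b1", "b2", "tau"))
    k5, k6, k7, b3, tau_a = (p[k] for k in ("k5", "k6", "k7", "b3", "tau_a"))

    def rhs(t, y, s):
        C = y[..., 0]
        B = y[..., 1]
        A = y[..., 2]
        dC = (k1 * B + b1) * (1.0 - C) - (k2 + k5 * A) * C
        dB = ((k3 * s * C + b2) * (1.0 - B) - k4 * B) / tau
        dA = ((k6 * s * C + b3) * (1.0 - A) - k7 * A) / tau_a
        return np.stack([dC, dB, dA], axis=-1)

    def jac(y, s):
        C, B, A = y[0], y[1], y[2]
        return np.array([
            [-(k1 * B + b1) - (k2 + k5 * A), k1 * (1.0 - C), -k5 * C],
            [k3 * s * (1.0 - B) / tau, -(k3 * s * C + b2 + k4) / tau, 0.0],
            [k6 * s * (1.0 - A) / tau_a, 0.0, -(k6 * s * C + b3 + k7) / tau_a],
        ])

    def sjac(y, s):
        C, B, A = y[0], y[1], y[2]
        return np.array([
            0.0,
            k3 * C * (1.0 - B) / tau,
            k6 * C * (1.0 - A) / tau_a,
        ])

    return ModelSpec(
        model_id="positive_negative",
        state_names=("C", "B", "A"),
        output_index=0,
        params=p,
        rhs=rhs,
        jacobian=jac,
        stimulus_jac=sjac,
        box_lo=np.zeros(3),
        box_hi=np.ones(3),
    )


# --- Hill (saturating-feedback) variants -----------------------------------

SINGLE_POSITIVE_HILL_SCHEMA = {
    **SINGLE_POSITIVE_SCHEMA,
    "KB": "halfsat",  # half-saturation of the B -> C activation
    "nB": "hill",
    "KC": "halfsat",  # half-saturation of the C -> B feedback
    "nC": "hill",
}

SINGLE_POSITIVE_HILL_NOMINAL = {
    "k1": 10.0, "k2": 1.0, "k3": 10.0, "k4": 1.0,
    "b1": 0.01, "b2": 0.001, "tau": 5.0,
    "KB": 0.3, "nB": 2.0, "KC": 0.3, "nC": 2.0,
}


def _build_single_positive_hill(params: Mapping[str, float]) -> ModelSpec:
    p = validate_params(SINGLE_POSITIVE_HILL_SCHEMA, params)
    k1, k2, k3, k4, b1, b2, tau = (p[k] for k in ("k1", "k2", "k3", "k4", "b1", "b2", "tau"))
    KB, nB, KC, nC = (p[k] for k in ("KB", "nB", "KC", "nC"))

    def rhs(t, y, s):
        C = y[..., 0]
        B = y[..., 1]
        dC = (k1 * hill(B, KB, nB) + b1) * (1.0 - C) - k2 * C
        dB = ((k3 * s * hill(C, KC, nC) + b2) * (1.0 - B) - k4 * B) / tau
        return np.stack([dC, dB], axis=-1)

    return ModelSpec(
        model_id="single_positive_hill",
        state_names=("C", "B"),
        output_index=0,
        params=p,
        rhs=rhs,
        box_lo=np.zeros(2),
        box_hi=np.ones(2),
    )


POSITIVE_POSITIVE_HILL_SCHEMA = {
    **POSITIVE_POSITIVE_SCHEMA,
    "KB": "halfsat", "nB": "hill", "KC": "halfsat", "nC": "hill",
    "KA": "halfsat", "nA": "hill",
}

POSITIVE_POSITIVE_HILL_NOMINAL = {
    **SINGLE_POSITIVE_HILL_NOMINAL,
    "k5": 10.0, "k6": 10.0, "k7": 1.0, "b3": 0.001, "tau_a": 0.5,
    "KA": 0.3, "nA": 2.0,
}


def _build_positive_positive_hill(params: Mapping[str, float]) -> ModelSpec:
    p = validate_params(POSITIVE_POSITIVE_HILL_SCHEMA, params)
    k1, k2, k3, k4, b1, b2, tau = (p[k] for k in ("k1", "k2", "k3", "k4", "b1", "b2", "tau"))
    k5, k6, k7, b3, tau_a = (p[k] for k in ("k5", "k6", "k7", "b3", "tau_a"))
    KB, nB, KC, nC, KA, nA = (p[k] for k in ("KB", "nB", "KC", "nC", "KA", "nA"))

    def rhs(t, y, s):
        C = y[..., 0]
        B = y[..., 1]
        A = y[..., 2]
        dC = (k1 * hill(B, KB, nB) + k5 * hill(A, KA, nA) + b1) * (1.0 - C) - k2 * C
        dB = ((k3 * s * hill(C, KC, nC) + b2) * (1.0 - B) - k4 * B) / tau
        dA = ((k6 * s * hill(C, KC, nC) + b3) * (1.0 - A) - k7 * A) / tau_a
        return np.stack([dC, dB, dA], axis=-1)

    return ModelSpec(
        model_id="positive_positive_hill",
        state_names=("C", "B", "A"),
        output_index=0,
        params=p,
        rhs=rhs,
        box_lo=np.zeros(3),
        box_hi=np.ones(3),
    )


# ---------------------------------------------------------------------------
# yeast pheromone-induced polarization (non-spatial)
# ---------------------------------------------------------------------------

YEAST_SCHEMA = {
    # receptor / ligand
    "kRL": "rate", "kRLm": "rate", "Rt": "conc",
    # G-protein cycle
    "kGa": "rate", "kGd": "rate", "kG1": "rate", "Gt": "conc",
    # Cdc24 membrane recruitment (free G-beta-gamma and Bem1 routes)
    "k24g": "rate", "K1": "halfsat", "q1": "hill",
    "kB24": "rate", "k24m": "rate", "kCla": "rate", "C24t": "conc",
    # Cdc42 activation
    "k42": "rate", "k42m": "rate", "C42t": "conc",
    # Bem1 recruitment (positive loop)
    "kB1": "rate", "K2": "halfsat", "q2": "hill", "kB1m": "rate", "B1t": "conc",
    # Cla4 negative loop
    "kCla4": "rate", "kCla4m": "rate", "Cla4t": "conc",
    # membrane-to-cytoplasm scale (surface-area / volume factor)
    "rho": "conc",
}

# Totals normalized to 1; time unit is the receptor turnover time.  Values
# chosen to give clearly separated active/inactive stationary outputs between
# high and low pheromone, with the Bem1 route providing the dominant
# (switch-forming) positive feedback.
YEAST_NOMINAL = {
    "kRL": 1.0, "kRLm": 1.0, "Rt": 1.0,
    "kGa": 2.0, "kGd": 1.0, "kG1": 5.0, "Gt": 1.0,
    "k24g": 0.2, "K1": 0.5, "q1": 4.0,
    "kB24": 4.0, "k24m": 1.0, "kCla": 1.0, "C24t": 1.0,
    "k42": 6.0, "k42m": 1.0, "C42t": 1.0,
    "kB1": 6.0, "K2": 0.5, "q2": 4.0, "kB1m": 1.0, "B1t": 1.0,
    "kCla4": 1.0, "kCla4m": 2.0, "Cla4t": 1.0,
    "rho": 1.0,
}

# [L] levels driving the active / inactive stationary states of the fixture
YEAST_L_HIGH = 2.0
YEAST_L_LOW = 0.01


def _build_yeast(params: Mapping[str, float]) -> ModelSpec:
    p = validate_params(YEAST_SCHEMA, params)
    kRL, kRLm, Rt = p["kRL"], p["kRLm"], p["Rt"]
    kGa, kGd, kG1, Gt = p["kGa"], p["kGd"], p["kG1"], p["Gt"]
    k24g, K1, q1 = p["k24g"], p["K1"], p["q1"]
    kB24, k24m, kCla, C24t = p["kB24"], p["k24m"], p["kCla"], p["C24t"]
    k42, k42m, C42t = p["k42"], p["k42m"], p["C42t"]
    kB1, K2, q2, kB1m, B1t = p["kB1"], p["K2"], p["q2"], p["kB1m"], p["B1t"]
    kCla4, kCla4m, Cla4t = p["kCla4"], p["kCla4m"], p["Cla4t"]
    rho = p["rho"]

    def rhs(t, y, s):
        RL = y[..., 0]
        Ga = y[..., 1]
        Gbg = y[..., 2]
        C24m = y[..., 3]
        C42a = y[..., 4]
        B1m = y[..., 5]
        Cl4a = y[..., 6]
        R = Rt - RL
        G = Gt - Gbg
        Gd = Gbg - Ga
        C24c = C24t - rho * C24m
        C42 = C42t - C42a
        B1c = B1t - rho * B1m
        Cl4 = Cla4t - Cl4a
        dRL = kRL * s * R - kRLm * RL
        dGa = kGa * RL * G - kGd * Ga
        dGbg = kGa * RL * G - kG1 * Gd * Gbg
        dC24m = (k24g * hill(Gbg, K1, q1) + kB24 * B1m) * C24c \
            - k24m * C24m - kCla * Cl4a * C24m
        dC42a = k42 * C24m * C42 - k42m * C42a
        dB1m = kB1 * hill(Gbg, K2, q2) * C42a * B1c - kB1m * B1m
        dCl4a = kCla4 * C42a * Cl4 - kCla4m * Cl4a
        return np.stack([dRL, dGa, dGbg, dC24m, dC42a, dB1m, dCl4a], axis=-1)

    # Gd = Gbg - Ga is a difference of two states rather than total-minus-state;
    # expressed with weights (+1 on Ga, -1 on Gbg) and total 0.
    pools = (
        ConservedPool("R", ("RL",), (1.0,), Rt),
        ConservedPool("G", ("Gbg",), (1.0,), Gt),
        ConservedPool("Gd", ("Ga", "Gbg"), (1.0, -1.0), 0.0),
        ConservedPool("Cdc42", ("Cdc42a",), (1.0,), C42t),
        ConservedPool("Cdc24c", ("Cdc24m",), (rho,), C24t),
        ConservedPool("Bem1c", ("Bem1m",), (rho,), B1t),
        ConservedPool("Cla4", ("Cla4a",), (1.0,), Cla4t),
    )

    hi = np.array([Rt, Gt, Gt, C24t / rho, C42t, B1t / rho, Cla4t])
    return ModelSpec(
        model_id="yeast_polarization",
        state_names=("RL", "Ga", "Gbg", "Cdc24m", "Cdc42a", "Bem1m", "Cla4a"),
        output_index=4,
        params=p,
        rhs=rhs,
        box_lo=np.zeros(7),
        box_hi=hi,
        pools=pools,
        stiff=True,
    )


# ---------------------------------------------------------------------------
# polymyxin-B resistance connector circuit (5 states, 13 parameters)
# ---------------------------------------------------------------------------

FCL_SCHEMA = {
    "a1": "rate",     # max transcription rate of the connector gene (pmrD)
    "K1": "halfsat",  # half-saturation of phospho-PhoP on the pmrD promoter
    "d1": "rate",     # pmrD mRNA degradation rate
    "t2": "rate",     # PmrD translation rate
    "d2": "rate",     # PmrD protein degradation rate
    "kph": "rate",    # PmrA phosphorylation rate (mild, basal activation)
    "kdeph": "rate",  # phospho-PmrA dephosphorylation rate
    "At": "conc",     # total PmrA
    "kon": "rate",    # PmrD + phospho-PmrA association (protection)
    "koff": "rate",   # protected-complex dissociation
    "a5": "rate",     # max transcription rate of pbgP
    "K5": "halfsat",  # half-saturation of active PmrA on the pbgP promoter
    "d5": "rate",     # pbgP mRNA degradation rate
}

# Mild PmrA activation (phosphorylation much slower than dephosphorylation)
# makes the circuit depend on connector-mediated protection; the slow complex
# dissociation is what sustains the output after the input drops.
FCL_NOMINAL = {
    "a1": 2.0, "K1": 0.5, "d1": 1.0,
    "t2": 0.5, "d2": 0.5,
    "kph": 0.05, "kdeph": 2.0, "At": 1.0,
    "kon": 1.0, "koff": 0.02,
    "a5": 2.0, "K5": 0.2, "d5": 0.3,
}

# relative weight of the direct (feedforward) input arm on the pbgP promoter;
# structural constant of the circuit, not a kinetic parameter
FCL_DIRECT_WEIGHT = 0.3


def _build_fcl(params: Mapping[str, float]) -> ModelSpec:
    p = validate_params(FCL_SCHEMA, params)
    a1, K1, d1 = p["a1"], p["K1"], p["d1"]
    t2, d2 = p["t2"], p["d2"]
    kph, kdeph, At = p["kph"], p["kdeph"], p["At"]
    kon, koff = p["kon"], p["koff"]
    a5, K5, d5 = p["a5"], p["K5"], p["d5"]
    w = FCL_DIRECT_WEIGHT

    def rhs(t, y, s):
        m1 = y[..., 0]   # pmrD mRNA
        D = y[..., 1]    # PmrD protein
        Ap = y[..., 2]   # free phospho-PmrA
        Cx = y[..., 3]   # protected PmrD:phospho-PmrA complex
        m5 = y[..., 4]   # pbgP mRNA
        A_free = At - Ap - Cx
        act = Ap + Cx    # transcriptionally active PmrA
        dm1 = a1 * s * s / (K1 * K1 + s * s) - d1 * m1
        dD = t2 * m1 - d2 * D - kon * D * Ap + koff * Cx
        dAp = kph * A_free - kdeph * Ap - kon * D * Ap + koff * Cx
        dCx = kon * D * Ap - koff * Cx
        dm5 = a5 * (act / (K5 + act) + w * s / (K1 + s)) - d5 * m5
        return np.stack([dm1, dD, dAp, dCx, dm5], axis=-1)

    pools = (ConservedPool("PmrA", ("PmrAp", "PmrD_PmrAp"), (1.0, 1.0), At),)
    hi = np.array([np.inf, np.inf, At, At, np.inf])
    return ModelSpec(
        model_id="polymyxin_fcl",
        state_names=("pmrD_mRNA", "PmrD", "PmrAp", "PmrD_PmrAp", "pbgP_mRNA"),
        output_index=4,
        params=p,
        rhs=rhs,
        box_lo=np.zeros(5),
        box_hi=hi,
        pools=pools,
        stiff=True,
    )


# ---------------------------------------------------------------------------
# registry
# ---------------------------------------------------------------------------

_BUILDERS: dict = {
    "single_positive": (_build_single_positive, SINGLE_POSITIVE_NOMINAL),
    "positive_positive": (_build_positive_positive, POSITIVE_POSITIVE_NOMINAL),
    "positive_negative": (_build_positive_negative, POSITIVE_NEGATIVE_NOMINAL),
    "single_positive_hill": (_build_single_positive_hill, SINGLE_POSITIVE_HILL_NOMINAL),
    "positive_positive_hill": (_build_positive_positive_hill, POSITIVE_POSITIVE_HILL_NOMINAL),
    "yeast_polarization": (_build_yeast, YEAST_NOMINAL),
    "polymyxin_fcl": (_build_fcl, FCL_NOMINAL),
}


def available_models() -> list:
    return sorted(_BUILDERS)


def nominal_params(model_id: str) -> dict:
    """Copy of the built-in nominal parameter set for ``model_id``."""
    if model_id not in _BUILDERS:
        raise KeyError(f"unknown model {model_id!r}; known: {', '.join(available_models())}")
    return dict(_BUILDERS[model_id][1])


def build_model(model_id: str, params: Mapping[str, float] | None = None,
                **overrides: float) -> ModelSpec:
    """Build a ModelSpec; ``params`` defaults to the nominal set, then overrides."""
    if model_id not in _BUILDERS:
        raise KeyError(f"unknown model {model_id!r}; known: {', '.join(available_models())}")
    builder, nominal = _BUILDERS[model_id]
    p = dict(nominal) if params is None else dict(params)
    p.update(overrides)
    return builder(p)


def register_model(model_id: str, builder: Callable, nominal: Mapping[str, float]):
    """Register a user circuit (same ModelSpec contract as the built-ins)."""
    if model_id in _BUILDERS:
        raise ValueError(f"model id {model_id!r} already registered")
    _BUILDERS[model_id] = (builder, dict(nominal))


# ---------------------------------------------------------------------------
# closed forms
# ---------------------------------------------------------------------------

def closed_form_no_feedback(params: Mapping[str, float], stimulus_level: float,
                            t, C0: float = None):
    """Output of the single-positive module with the loop influence removed.

    With the loop-to-output association constant ``k1 = 0`` the output
    equation decouples: ``dC/dt = b1*(1 - C) - k2*C``, a pure exponential
    relaxation at rate ``b1 + k2`` toward ``b1 / (b1 + k2)``.  This is the
    no-feedback reference against which slow loop-carried transients are
    judged: a loop only slows the response if its own time scale is slower
    than ``1 / (b1 + k2)``.
    """
    p = validate_params(SINGLE_POSITIVE_SCHEMA, params)
    if p["k1"] != 0.0:
        raise ValueError("closed form requires feedback strength k1 == 0")
    if stimulus_level < 0:
        raise ValueError("stimulus level must be nonnegative")
    rate = p["b1"] + p["k2"]
    Cinf = p["b1"] / rate if rate > 0 else 0.0
    if C0 is None:
        C0 = Cinf
    t = np.asarray(t, dtype=float)
    return Cinf + (C0 - Cinf) * np.exp(-rate * t)
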