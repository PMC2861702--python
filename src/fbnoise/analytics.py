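"""Closed-form machinery: linear stability, mode contributions, analytic Q.

Three layers, all built on the Jacobian of the noise-free system at a
stationary state:

* **Linearization** — eigenvalues sorted slow-to-fast by ``|Re|``, eigenvector
  output components, and the mode coefficients of a given initial
  displacement.  The linearized transient of the output coordinate is a sum
  of (possibly few) exponentials; the activation/deactivation step responses
  of the feedback modules are well described by it near the destination
  state.

* **Mode contribution measures** — the time-integrated, gap-normalized weight
  of the loop-carried eigenmodes in the output transient.  A transient whose
  loop modes carry a lot of integrated mass traverses its gap slowly;
  comparing this measure between module architectures on matched parameters
  quantifies statements like "an additional positive loop accelerates
  activation" or "a negative loop sustains deactivation".

* **Analytic noise amplification** — a fluctuation-dissipation estimate of
  the noise amplification rate ``Q`` for the single-positive-loop module
  (white-noise limit of the piecewise-constant input, valid for small, fast
  noise), plus an *exact* stationary-variance oracle for any linearized
  module driven by the piecewise-constant uniform input process, computed
  from the per-segment matrix propagator (discrete Lyapunov fixed point).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.linalg import expm, solve, solve_continuous_lyapunov, solve_discrete_lyapunov

from .models import (
    ModelSpec,
    SINGLE_POSITIVE_SCHEMA,
    build_model,
    fd_jacobian,
    model_jacobian,
    validate_params,
)
from .signals import CompositeSignal, decompose_fast_slow
from .simulate import Trajectory, integrate

__all__ = [
    "LinearAnalysis",
    "FDTResult",
    "fd_jacobian",
    "linearize",
    "deactivation_approximation",
    "contribution_measure",
    "transient_loop_contribution",
    "fdt_noise_amplification",
    "lyapunov_oracle_Q",
    "two_timescale_zero_order",
]


def _sorted_eig(J: np.ndarray):
    lam, V = np.linalg.eig(J)
    # ascending |Re|, ties by imaginary part then original index
    order = np.lexsort((np.arange(len(lam)), lam.imag, np.abs(lam.real)))
    return lam[order], V[:, order]


@dataclass
class LinearAnalysis:
    fixed_point: np.ndarray
    stimulus_level: float
    jacobian: np.ndarray
    eigenvalues: np.ndarray          # sorted ascending |Re|
    eigenvectors: np.ndarray         # columns matched to eigenvalues
    output_index: int
    output_components: np.ndarray    # eigenvector components on the output coordinate
    coefficients: np.ndarray | None  # mode coefficients of the initial displacement
    stable: bool
    oscillatory: bool
    defective: bool
    model_id: str = ""

    @property
    def slow_mask(self) -> np.ndarray:
        """Slow eigenmode cluster: ``|Re lambda|`` below the geometric mean
        of the slowest and fastest decay rates."""
        rates = np.abs(self.eigenvalues.real)
        lo, hi = rates.min(), rates.max()
        if hi <= lo * (1.0 + 1e-9):
            return np.ones_like(rates, dtype=bool)
        cut = np.sqrt(lo * hi)
        return rates <= cut * (1.0 + 1e-12)


def linearize(model: ModelSpec, fixed_point, stimulus_level: float,
              displacement=None, residual_tol: float = 1e-8) -> LinearAnalysis:
    """Eigen-analysis of the Jacobian at a stationary state.

    ``displacement`` (optional) is the initial offset from the fixed point
    whose transient is being studied; its expansion coefficients on the
    eigenbasis are solved and stored.
    """
    fp = np.asarray(fixed_point, dtype=float)
    res = float(np.max(np.abs(model.rhs(0.0, fp, stimulus_level))))
    if res > residual_tol:
        raise ValueError(f"fixed-point residual {res:.2e} exceeds {residual_tol:g}")
    J = model_jacobian(model, fp, stimulus_level)
    lam, V = _sorted_eig(J)
    # eigenpair residual check
    for i in range(len(lam)):
        r = np.max(np.abs(J @ V[:, i] - lam[i] * V[:, i]))
        if r > 1e-10 * max(1.0, np.max(np.abs(J))):
            raise RuntimeError("eigenpair residual exceeds tolerance")
    defective = np.linalg.cond(V) > 1e10
    coeffs = None
    if displacement is not None and not defective:
        coeffs = solve(V, np.asarray(displacement, dtype=float))
    return LinearAnalysis(
        fixed_point=fp,
        stimulus_level=stimulus_level,
        jacobian=J,
        eigenvalues=lam,
        eigenvectors=V,
        output_index=model.output_index,
        output_components=V[model.output_index, :],
        coefficients=coeffs,
        stable=bool(np.all(lam.real < 0)),
        oscillatory=bool(np.any(np.abs(lam.imag) > 1e-10)),
        defective=bool(defective),
        model_id=model.model_id,
    )


def deactivation_approximation(analysis: LinearAnalysis, t):
    """Multi-exponential approximation of the output transient.

    ``output(t) = fp_out + sum_i c_i * v_i[out] * exp(lambda_i t)`` — the
    linearized step response around the destination stationary state.  Only
    defined for real (non-oscillatory) mode structures, which is the regime
    of all built-in fixtures.
    """
    if analysis.oscillatory:
        raise ValueError("mode approximation assumes real eigenvalues")
    if analysis.coefficients is None:
        raise ValueError("analysis carries no initial displacement coefficients")
    t = np.asarray(t, dtype=float)
    scalar = t.ndim == 0
    tvec = np.atleast_1d(t)
    terms = (analysis.coefficients * analysis.output_components)[None, :] \
        * np.exp(np.multiply.outer(tvec, analysis.eigenvalues))
    out = analysis.fixed_point[analysis.output_index] + terms.sum(axis=-1).real
    return float(out[0]) if scalar else out


def contribution_measure(analysis: LinearAnalysis, gap: float = 1.0) -> float:
    """Loop-mode contribution to the linearized output transient.

    The linearized output transient is ``sum_i c_i v_i[out] exp(lambda_i t)``.
    One eigenmode — the one whose (unit) eigenvector points most strongly
    along the output coordinate — represents the output's own relaxation;
    every other mode is carried into the output by the feedback loops.  The
    measure is the time-integrated magnitude of those loop-carried terms,

        sum_{i != output mode} |c_i v_i[out] / Re(lambda_i)| / gap,

    normalized by the output gap between the two stationary states.  Large
    values mean the loops hold the output away from its destination for a
    long time relative to the gap (slow traversal); matched comparisons of
    this measure between architectures quantify how an extra loop speeds up
    or sustains a transient.
    """
    if analysis.defective:
        raise ValueError("Jacobian numerically defective; contributions suppressed")
    if analysis.coefficients is None:
        raise ValueError("analysis carries no initial displacement coefficients")
    if not analysis.stable:
        raise ValueError("contribution measure requires a stable fixed point")
    if gap <= 0:
        raise ValueError("gap must be positive")
    out_mode = int(np.argmax(np.abs(analysis.eigenvectors[analysis.output_index, :])))
    mass = np.abs(analysis.coefficients * analysis.output_components
                  / analysis.eigenvalues.real)
    keep = np.ones(len(mass), dtype=bool)
    keep[out_mode] = False
    return float(mass[keep].sum() / gap)


def transient_loop_contribution(model: ModelSpec, s_from: np.ndarray,
                                s_to: np.ndarray, level: float,
                                gap: float) -> float:
    """Loop-carried contribution for the step transient ``s_from -> s_to``
    under constant stimulus ``level`` (linearized at the destination)."""
    ana = linearize(model, s_to, level,
                    displacement=np.asarray(s_from, float) - np.asarray(s_to, float))
    return contribution_measure(ana, gap=gap)


# ---------------------------------------------------------------------------
# analytic noise amplification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FDTResult:
    Q_analytic: float
    flags: dict = field(default_factory=dict)

    @property
    def in_regime(self) -> bool:
        return all(self.flags.values())


def _active_fixed_point(model: ModelSpec, S0: float) -> np.ndarray:
    from .simulate import integrate_to_stationarity
    from scipy.optimize import root

    hi = np.where(np.isfinite(model.box_hi), model.box_hi, 1.0)
    guess, _ = integrate_to_stationarity(model, S0, hi, tol=1e-10)
    sol = root(lambda y: model.rhs(0.0, y, S0), guess, method="hybr", tol=1e-13)
    return sol.x if sol.success else guess


def fdt_noise_amplification(params, gamma: float, S0: float = 1.0,
                            delta: float = None) -> FDTResult:
    """Closed-form noise amplification rate of the single-positive module.

    Fluctuation-dissipation estimate at the active state: the
    piecewise-constant uniform input (segment length ``1/gamma``, variance
    ``delta^2/3``) is approximated by white noise of matching integrated
    autocovariance, and the stationary output variance of the linearized
    2x2 system is solved in closed form:

        Var[C] = sigma^2 * Delta * (J01 * g)^2 / (-2 * tr(J) * det(J))

    with ``g`` the stimulus sensitivity of the loop equation.  Q follows by
    dividing the output CV by the input CV ``delta/(sqrt(3) S0)`` — the
    amplitude cancels, so the estimate is amplitude-free.  Validity
    (small noise, noise faster than the slowest mode, stable active state)
    is recorded as flags; out-of-regime evaluation returns a value anyway.
    """
    p = validate_params(SINGLE_POSITIVE_SCHEMA, params)
    if gamma <= 0:
        raise ValueError("gamma must be positive")
    model = build_model("single_positive", p)
    fp = _active_fixed_point(model, S0)
    J = model_jacobian(model, fp, S0)
    gvec = model.stimulus_jac(fp, S0)
    tr = float(np.trace(J))
    det = float(np.linalg.det(J))
    lam = np.linalg.eigvals(J)
    Delta = 1.0 / gamma
    stable = bool(np.all(lam.real < 0))
    C_star = fp[model.output_index]
    if stable and C_star > 0:
        var_over_sigma2 = Delta * (J[0, 1] * gvec[1]) ** 2 / (-2.0 * tr * det)
        Q = float(np.sqrt(var_over_sigma2) / C_star * S0)
    else:
        Q = float("nan")
    flags = {
        "stable_active_state": stable,
        "noise_faster_than_slowest_mode": bool(np.max(np.abs(lam.real)) * Delta <= 0.5),
    }
    if delta is not None:
        flags["small_noise"] = bool(delta / S0 <= 0.2)
    return FDTResult(Q_analytic=Q, flags=flags)


def lyapunov_oracle_Q(model: ModelSpec, fixed_point, S0: float, delta: float,
                      gamma: float) -> float:
    """Exact stationary Q of the linearized module under piecewise noise.

    Over one noise segment of length ``Delta = 1/gamma`` the linearized
    deviation obeys ``x_{n+1} = F x_n + h eta_n`` with ``F = exp(J Delta)``
    and ``h = J^{-1}(F - I) g``; the stationary segment-start covariance is
    the discrete Lyapunov fixed point, and the within-segment time average
    is evaluated exactly via continuous Lyapunov identities.  Q uses the
    exact input CV ``delta / (sqrt(3) S0)``.
    """
    fp = np.asarray(fixed_point, dtype=float)
    J = model_jacobian(model, fp, S0)
    lam = np.linalg.eigvals(J)
    if np.any(lam.real >= 0):
        raise ValueError("lyapunov oracle requires a stable linearization")
    if model.stimulus_jac is not None:
        g = np.asarray(model.stimulus_jac(fp, S0), dtype=float)
    else:
        h_s = max(1e-6, 1e-6 * abs(S0))
        g = (model.rhs(0.0, fp, S0 + h_s) - model.rhs(0.0, fp, S0 - h_s)) / (2 * h_s)
    Delta = 1.0 / gamma
    sigma2 = delta**2 / 3.0
    F = expm(J * Delta)
    Iden = np.eye(J.shape[0])
    W = solve(J, F - Iden)           # = J^{-1}(F - I) = int_0^Delta e^{Jt} dt
    h = W @ g
    Sigma0 = solve_discrete_lyapunov(F, sigma2 * np.outer(h, h))
    # time-averaged covariance over a segment
    Xa = solve_continuous_lyapunov(J, F @ Sigma0 @ F.T - Sigma0)
    gg = np.outer(g, g)
    X1 = solve_continuous_lyapunov(J, F @ gg @ F.T - gg)
    inner = X1 - W @ gg - gg @ W.T + Delta * gg
    Jin = np.linalg.inv(J)
    Xphi = Jin @ inner @ Jin.T
    Vbar = (Xa + sigma2 * Xphi) / Delta
    k = model.output_index
    var_out = float(Vbar[k, k])
    cv_out = np.sqrt(max(var_out, 0.0)) / fp[k]
    cv_in = delta / (np.sqrt(3.0) * S0)
    return float(cv_out / cv_in)


# ---------------------------------------------------------------------------
# two-time-scale zero-order solution
# ---------------------------------------------------------------------------

def two_timescale_zero_order(model: ModelSpec, signal: CompositeSignal,
                             initial_state, duration: float,
                             **solver_options) -> Trajectory:
    """Zero-order slow solution of the two-time-scale expansion.

    For an input split into slow and fast-tagged parts, the zero-order slow
    equation is the model driven by the slow part alone: the fast component
    does not appear at leading order, which is the analytic statement that
    these modules low-pass filter fast input noise.  Returns the zero-order
    trajectory (integrated with the same machinery as the full system).
    """
    slow, _fast = decompose_fast_slow(signal)
    return integrate(model, slow, initial_state, duration, **solver_options)
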