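"""Canned studies: the package's headline computational protocols.

Each function runs one complete, self-contained study — the kind of numeric
experiment the package exists to perform — and returns a plain dict of
scalars.  They are used by the acceptance machinery and are convenient
entry points for interactive exploration.

All randomness derives from a single integer ``base_seed``; distinct studies
offset it by fixed strides so they can be run in any combination while
remaining reproducible.  Problem sizes (grid resolution, replicate counts,
analysis windows) come from the packaged fixture files.
"""

from __future__ import annotations

import numpy as np

from .analytics import (
    fdt_noise_amplification,
    linearize,
    lyapunov_oracle_Q,
    contribution_measure,
    two_timescale_zero_order,
)
from .config import load_fixture
from .experiments import (
    NoiseSpec,
    compare_modules,
    geometric_grid,
    sweep_frequency,
    sweep_parameter,
    trend_test,
)
from .models import build_model, closed_form_no_feedback, nominal_params
from .noisemetrics import coefficient_of_variation, ensemble_Q
from .signals import (
    CompositeSignal,
    ConstantSignal,
    PiecewiseNoiseSignal,
    SquareWaveSignal,
    make_noisy_signal,
)
from .simulate import integrate
from .timescales import compute_steady_states, measure_timescales

__all__ = [
    "headline_parameter_study",
    "frequency_study",
    "architecture_study",
    "q_agreement_study",
    "closed_form_study",
    "two_timescale_study",
    "contribution_inequality_study",
    "module_comparison_study",
    "estimator_study",
]


def _noise_from_fixture(fx) -> NoiseSpec:
    n = fx["noise"]
    return NoiseSpec(S0=n["S0"], delta=n["delta"], gamma=n["gamma"],
                     S_low=n["S_low"])


def _fixture_sweeps(fixture_name: str, base_seed: int) -> dict:
    """Spearman rho of Q vs T for every sweep parameter of a fixture."""
    fx = load_fixture(fixture_name)
    model_id = fx["model"]["id"]
    params = fx["model"].get("params") or nominal_params(model_id)
    noise = _noise_from_fixture(fx)
    rhos = {}
    for j, par in enumerate(fx["sweep_params"]):
        grid = geometric_grid(params[par], fx.get("fold", 2.0), 10)
        pts = sweep_parameter(model_id, par, grid, noise,
                              n_reps=fx.get("n_reps", 20),
                              base_seed=base_seed + 1000 * j,
                              base_params=params,
                              window_periods=fx.get("window_periods", 1000))
        rhos[par] = trend_test(pts).rho
    return rhos


def headline_parameter_study(base_seed: int) -> dict:
    """Inverse Q-T relation for the single-positive module, one sweep per
    kinetic parameter (10-point geometric grids, fixture replicate counts)."""
    return _fixture_sweeps("single_positive_nominal", base_seed)


def frequency_study(base_seed: int) -> dict:
    """Inverse Q-T relation along noise-frequency sweeps at fixed kinetics,
    one sweep per fixture kinetic set."""
    fx = load_fixture("single_positive_frequency_sets")
    base = nominal_params(fx["model"]["id"])
    noise = _noise_from_fixture(fx)
    gammas = [float(g) for g in fx["gamma_grid"]]
    rhos = {}
    for j, (name, overrides) in enumerate(sorted(fx["sets"].items())):
        pts = sweep_frequency(fx["model"]["id"], gammas, noise,
                              n_reps=fx.get("n_reps", 20),
                              base_seed=base_seed + 1000 * j,
                              base_params={**base, **overrides},
                              window_periods=fx.get("window_periods", 1000))
        rhos[name] = trend_test(pts).rho
    return rhos


ARCHITECTURE_FIXTURES = (
    "positive_positive_nominal",
    "positive_negative_nominal",
    "single_positive_hill_nominal",
    "positive_positive_hill_nominal",
    "yeast_polarization_nominal",
    "polymyxin_fcl_nominal",
)


def architecture_study(base_seed: int, fixtures=ARCHITECTURE_FIXTURES) -> dict:
    """Inverse Q-T sweeps for every other architecture fixture."""
    out = {}
    for i, name in enumerate(fixtures):
        out[name] = _fixture_sweeps(name, base_seed + 100_000 * (i + 1))
    return out


# fast-noise, small-amplitude conditions under which the linearized (FDT)
# description of the single-positive module applies
Q_AGREEMENT_FIXTURES = (
    {"gamma": 25.0, "delta": 0.05, "overrides": {}},
    {"gamma": 30.0, "delta": 0.10, "overrides": {}},
    {"gamma": 40.0, "delta": 0.15, "overrides": {}},
    {"gamma": 30.0, "delta": 0.10, "overrides": {"k1": 15.0}},
    {"gamma": 35.0, "delta": 0.10, "overrides": {"tau": 8.0}},
)


def q_agreement_study(base_seed: int, n_reps: int = 10) -> dict:
    """Analytic (FDT), exact-propagator, and Monte-Carlo Q, pairwise.

    Returns the worst pairwise relative difference across the in-regime
    fixtures plus the per-fixture triples.
    """
    rows = []
    worst = 0.0
    for i, fx in enumerate(Q_AGREEMENT_FIXTURES):
        params = {**nominal_params("single_positive"), **fx["overrides"]}
        model = build_model("single_positive", params)
        ss = compute_steady_states(model, 0.0, 1.0)
        gamma, delta = fx["gamma"], fx["delta"]
        mc = ensemble_Q(model, 1.0, delta, gamma, n_reps=n_reps,
                        base_seed=base_seed + 100 * i, initial_state=ss.s_on,
                        s_off_output=float(ss.s_off[0])).mean_Q
        lyap = lyapunov_oracle_Q(model, ss.s_on, 1.0, delta, gamma)
        fdt = fdt_noise_amplification(params, gamma, 1.0, delta).Q_analytic
        triple = {"mc": mc, "lyapunov": lyap, "fdt": fdt}
        pair = max(abs(a - b) / min(a, b)
                   for a in triple.values() for b in triple.values())
        worst = max(worst, pair)
        rows.append(triple | {"gamma": gamma, "delta": delta,
                              "max_pairwise_rel_diff": pair})
    return {"max_pairwise_rel_diff": worst, "fixtures": rows}


def scalar_filter_oracle_error(tau_f: float = 2.0, S0: float = 1.0,
                               delta: float = 0.2, gamma: float = 0.5) -> float:
    """|exact-propagator Q - hand-derived closed form| for the first-order
    low-pass filter dy/dt = (u - y)/tau_f driven by piecewise noise."""
    from .models import ModelSpec

    def rhs(t, y, s):
        return np.stack([(s - y[..., 0]) / tau_f], axis=-1)

    filt = ModelSpec(model_id="user_plugin", state_names=("y",),
                     output_index=0, params={"tau_f": tau_f}, rhs=rhs,
                     box_lo=np.array([-np.inf]), box_hi=np.array([np.inf]),
                     stimulus_jac=lambda y, s: np.array([1.0 / tau_f]))
    a = 1.0 / tau_f
    Delta = 1.0 / gamma
    s2 = delta**2 / 3.0
    E = np.exp(-a * Delta)
    Vb = s2 * (1 - E) ** 2 / (1 - E**2)
    Vbar = Vb * (1 - E**2) / (2 * a * Delta) \
        + s2 * (Delta - 2 * (1 - E) / a + (1 - E**2) / (2 * a)) / Delta
    Q_hand = float(np.sqrt(Vbar) / np.sqrt(s2))
    Q_oracle = lyapunov_oracle_Q(filt, np.array([S0]), S0, delta, gamma)
    return abs(Q_hand - Q_oracle)


def closed_form_study(n_times: int = 20) -> dict:
    """No-feedback relaxation: integrator vs the exponential closed form."""
    params = {**nominal_params("single_positive"), "k1": 0.0}
    model = build_model("single_positive", params)
    C0 = 0.9
    traj = integrate(model, ConstantSignal(0.0, 25.0), np.array([C0, 0.5]),
                     20.0, rtol=1e-11, atol=1e-13)
    times = np.linspace(0.0, 20.0, n_times)
    num = np.interp(times, traj.times, traj.output(0))
    ana = closed_form_no_feedback(params, 0.0, times, C0=C0)
    return {"max_abs_err": float(np.max(np.abs(num - ana))), "n": n_times}


def two_timescale_study(base_seed: int, eps: float = 0.1,
                        duration: float = 8.0) -> dict:
    """Zero-order (slow) solution versus the full system.

    Two checks: (a) with a fast-only noise input the zero-order solution is
    *identical* to the noise-free system (the fast part never enters it);
    (b) with a deterministic zero-mean fast component the full-vs-zero-order
    sup error halves when eps is halved (first-order accuracy of the
    expansion); the ratio between eps and eps/2 is returned.
    """
    model = build_model("single_positive")
    ss = compute_steady_states(model, 0.0, 1.0)

    # (a) identity: zero-order with fast noise == noise-free trajectory
    from .signals import CenteredNoiseSignal

    fast_noise = CenteredNoiseSignal(delta=0.3, gamma=1.0 / eps,
                                     duration=duration, seed=base_seed)
    comp = CompositeSignal((ConstantSignal(1.0, duration), fast_noise),
                           ("slow", "fast"), duration)
    zero = two_timescale_zero_order(model, comp, ss.s_on, duration)
    ref = integrate(model, ConstantSignal(1.0, duration), ss.s_on, duration)
    ident = float(np.max(np.abs(
        zero.output(0) - np.interp(zero.times, ref.times, ref.output(0)))))

    # (b) eps-refinement with a deterministic fast square wave
    errs = {}
    for e in (eps, eps / 2.0):
        fast = SquareWaveSignal(amplitude=0.3, period=e, duration=duration)
        sig = CompositeSignal((ConstantSignal(1.0, duration), fast),
                              ("slow", "fast"), duration)
        full = integrate(model, sig, ss.s_on, duration, rtol=1e-10, atol=1e-12)
        z = two_timescale_zero_order(model, sig, ss.s_on, duration,
                                     rtol=1e-10, atol=1e-12)
        zi = np.interp(full.times, z.times, z.output(0))
        errs[e] = float(np.max(np.abs(full.output(0) - zi)))
    return {"fast_noise_identity_sup_err": ident,
            "error_ratio": errs[eps] / errs[eps / 2.0],
            "eps": eps}


def _loop_contribution(model, steady, which: str) -> float:
    if which == "act":
        src, dst, level = steady.s_off, steady.s_on, steady.S_high
    else:
        src, dst, level = steady.s_on, steady.s_off, steady.S_low
    ana = linearize(model, dst, level,
                    displacement=np.asarray(src) - np.asarray(dst))
    return contribution_measure(ana, gap=abs(steady.gap))


def contribution_inequality_study(base_seed: int, n_samples: int = 200) -> dict:
    """Loop-contribution inequalities across architectures, randomized.

    For each admissible random parameter set (kinetics varied 2-fold around
    nominal, slow loop time scale in [4, 8]) the matched architectures are
    compared in their regimes: slow-slow second loop (time scales matched
    within 10%), fast second loop (tau_a in [0.05, 0.2], at least ~20x faster
    than the slow loop), and slow negative loop (tau_a = tau).  Counts
    violations of each printed inequality; the fast-slow deactivation ratio
    is also required to stay in (0.6, 1).
    """
    rng = np.random.default_rng(base_seed)
    base = nominal_params("single_positive")

    def logu(lo, hi):
        return float(np.exp(rng.uniform(np.log(lo), np.log(hi))))

    keys = ["act_two_slow_loops_lt_single", "act_fast_slow_lt_single",
            "act_fast_negative_gt_single", "act_slow_negative_lt_single",
            "deact_two_slow_loops_gt_single", "deact_fast_slow_lt_single",
            "deact_fast_slow_ratio_band", "deact_fast_negative_gt_single"]
    violations = dict.fromkeys(keys, 0)
    used = 0
    attempts = 0
    while used < n_samples and attempts < 4 * n_samples:
        attempts += 1
        p = dict(base)
        for k in ("k1", "k2", "k3", "k4"):
            p[k] = base[k] * logu(0.5, 2.0)
        p["tau"] = logu(4.0, 8.0)
        extra = {"k5": p["k1"], "k6": p["k3"], "k7": p["k4"], "b3": p["b2"]}
        cases = {
            "ppss": ("positive_positive",
                     {**extra, "tau_a": p["tau"] * logu(0.9, 1.1)}),
            "ppfs": ("positive_positive", {**extra, "tau_a": logu(0.05, 0.2)}),
            "pnf": ("positive_negative",
                    {**extra, "k5": 2.0 * logu(1.0, 2.0),
                     "tau_a": logu(0.05, 0.2)}),
            "pns": ("positive_negative",
                    {**extra, "k5": 2.0 * logu(1.0, 2.0), "tau_a": p["tau"]}),
        }
        try:
            sp = build_model("single_positive", p)
            ss = compute_steady_states(sp, 0.0, 1.0)
            a_sp = _loop_contribution(sp, ss, "act")
            d_sp = _loop_contribution(sp, ss, "deact")
            res = {}
            for name, (mid, ex) in cases.items():
                m = build_model(mid, {**p, **ex})
                ssm = compute_steady_states(m, 0.0, 1.0)
                res[name] = (_loop_contribution(m, ssm, "act"),
                             _loop_contribution(m, ssm, "deact"))
        except Exception:
            continue
        used += 1
        checks = {
            "act_two_slow_loops_lt_single": res["ppss"][0] < a_sp,
            "act_fast_slow_lt_single": res["ppfs"][0] < a_sp,
            "act_fast_negative_gt_single": res["pnf"][0] > a_sp,
            "act_slow_negative_lt_single": res["pns"][0] < a_sp,
            "deact_two_slow_loops_gt_single": res["ppss"][1] > d_sp,
            "deact_fast_slow_lt_single": res["ppfs"][1] < d_sp,
            "deact_fast_slow_ratio_band": 0.6 < res["ppfs"][1] / d_sp < 1.0,
            "deact_fast_negative_gt_single": res["pnf"][1] > d_sp,
        }
        for key, ok in checks.items():
            if not ok:
                violations[key] += 1
    return {"n_samples": used, "violations": violations,
            "total_violations": int(sum(violations.values()))}


def module_comparison_study(theta: float = 0.9, gamma: float = 1.0) -> dict:
    """Matched-parameter time-scale comparisons plus monotonicity grids.

    Checks (all on the shared single-positive kinetics): additional positive
    loop shortens activation; slow-slow second loop and the negative loop
    lengthen deactivation; and on 10-point geometric grids t_act decreases
    while t_deact increases in both association constants, in all three
    architectures.  Returns the comparison table values and the count of
    violated relations.
    """
    df = compare_modules(gamma=gamma, theta=theta)
    row = {r["variant"]: r for _, r in df.iterrows()}
    sp = row["single_positive"]
    checks = {
        "pp_fast_slow_faster_activation":
            row["positive_positive_fast_slow"]["t_act"] < sp["t_act"],
        "pp_slow_slow_faster_activation":
            row["positive_positive_slow_slow"]["t_act"] < sp["t_act"],
        "pp_slow_slow_slower_deactivation":
            row["positive_positive_slow_slow"]["t_deact"] > sp["t_deact"],
        "pn_fast_slower_deactivation":
            row["positive_negative_fast"]["t_deact"] > sp["t_deact"],
        "pn_slow_slower_deactivation":
            row["positive_negative_slow"]["t_deact"] > sp["t_deact"],
    }
    mono_violations = 0
    for mid in ("single_positive", "positive_positive", "positive_negative"):
        nom = nominal_params(mid)
        for par in ("k1", "k3"):
            t_act, t_deact = [], []
            for v in geometric_grid(nom[par], 2.0, 10):
                m = build_model(mid, {**nom, par: float(v)})
                ts = measure_timescales(m, 0.0, 1.0, gamma, theta)
                t_act.append(ts.t_act)
                t_deact.append(ts.t_deact)
            if not np.all(np.diff(t_act) < 0):
                mono_violations += 1
            if not np.all(np.diff(t_deact) > 0):
                mono_violations += 1
    return {
        "table": {k: {"t_act": float(r["t_act"]), "t_deact": float(r["t_deact"]),
                      "T": float(r["T"])} for k, r in row.items()},
        "comparison_violations": int(sum(not ok for ok in checks.values())),
        "monotonicity_violations": int(mono_violations),
        "checks": checks,
    }


def estimator_study(base_seed: int) -> dict:
    """Sanity of the noise and Q estimators.

    (a) CV of the piecewise-uniform signal at 1e5 segments vs the exact
    delta/(sqrt(3) S0); (b) Q invariance under rescaling of the output
    series; (c) SEM ~ 1/sqrt(n): mean SEM over disjoint 10-replicate
    ensembles divided by mean SEM of 40-replicate ensembles.
    """
    sig = make_noisy_signal(1.0, 0.5, 1.0, 1e5, seed=base_seed)
    cv = coefficient_of_variation(sig.values)
    cv_err = abs(cv - 0.5 / np.sqrt(3.0)) / (0.5 / np.sqrt(3.0))

    rng = np.random.default_rng(base_seed + 1)
    series = rng.uniform(0.5, 1.5, 1000)
    scale_err = abs(coefficient_of_variation(3.7 * series)
                    - coefficient_of_variation(series))

    model = build_model("single_positive")
    ss = compute_steady_states(model, 0.0, 1.0)

    def mean_sem(n_reps, groups, seed0):
        vals = [ensemble_Q(model, 1.0, 0.3, 1.0, n_reps=n_reps,
                           base_seed=seed0 + 1000 * g, initial_state=ss.s_on,
                           window_periods=400).sem_Q for g in range(groups)]
        return float(np.mean(vals))

    ratio = mean_sem(10, 8, base_seed + 10) / mean_sem(40, 2, base_seed + 20_000)
    return {"signal_cv_rel_err": float(cv_err),
            "cv_scale_invariance_abs_err": float(scale_err),
            "sem_ratio_10_vs_40": float(ratio)}
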