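"""Linearization, contribution measures, analytic Q, two-time-scale."""

import numpy as np
import pytest

import fbnoise as fb
from fbnoise.analytics import (
    contribution_measure,
    deactivation_approximation,
    fd_jacobian,
    fdt_noise_amplification,
    linearize,
    lyapunov_oracle_Q,
    two_timescale_zero_order,
)
from fbnoise.models import ModelSpec
from fbnoise.signals import (
    CenteredNoiseSignal,
    CompositeSignal,
    ConstantSignal,
    SquareWaveSignal,
)


class TestLinearize:
    def test_decoupled_system_eigenvalues_are_relaxation_rates(self):
        """With the output decoupled from the loop the Jacobian is triangular:
        eigenvalues are minus the two species' individual relaxation rates."""
        params = {**fb.nominal_params("single_positive"), "k1": 0.0}
        model = fb.build_model("single_positive", params)
        y, _ = fb.integrate_to_stationarity(model, 1.0, np.array([0.5, 0.5]),
                                            tol=1e-11)
        ana = linearize(model, y, 1.0)
        b1, k2, b2, k4, k3, tau = (params[k] for k in
                                   ("b1", "k2", "b2", "k4", "k3", "tau"))
        expected = sorted([b1 + k2, (k3 * y[0] + b2 + k4) / tau])
        got = sorted(np.abs(ana.eigenvalues.real))
        assert np.allclose(got, expected, rtol=1e-8)

    @pytest.mark.parametrize("model_id", ["single_positive",
                                          "positive_positive",
                                          "positive_negative"])
    def test_analytic_and_fd_jacobians_agree(self, model_id):
        model = fb.build_model(model_id)
        rng = np.random.default_rng(0)
        for _ in range(5):
            y = rng.uniform(0.05, 0.95, model.state_dim)
            s = rng.uniform(0.0, 1.5)
            assert np.max(np.abs(model.jacobian(y, s)
                                 - fd_jacobian(model, y, s))) < 1e-6

    def test_oscillatory_pair_flagged(self):
        rot = ModelSpec(
            model_id="user_plugin", state_names=("x", "y"), output_index=0,
            params={},
            rhs=lambda t, y, s: np.stack(
                [-0.1 * y[..., 0] - y[..., 1], y[..., 0] - 0.1 * y[..., 1]],
                axis=-1),
            box_lo=np.array([-np.inf, -np.inf]),
            box_hi=np.array([np.inf, np.inf]))
        ana = linearize(rot, np.zeros(2), 0.0)
        assert ana.oscillatory
        with pytest.raises(ValueError, match="real"):
            deactivation_approximation(ana, 1.0)

    def test_bad_fixed_point_rejected(self, sp_model):
        with pytest.raises(ValueError, match="residual"):
            linearize(sp_model, np.array([0.5, 0.5]), 1.0)

    def test_eigen_sorted_slow_first(self, sp_model, sp_steady):
        ana = linearize(sp_model, sp_steady.s_on, 1.0)
        rates = np.abs(ana.eigenvalues.real)
        assert np.all(np.diff(rates) >= 0)
        assert ana.stable


class TestDeactivationApproximation:
    def test_t_zero_recovers_initial_displacement(self, sp_model, sp_steady):
        disp = sp_steady.s_on - sp_steady.s_off
        ana = linearize(sp_model, sp_steady.s_off, 0.0, displacement=disp)
        val = deactivation_approximation(ana, 0.0)
        assert val == pytest.approx(sp_steady.s_on[0], abs=1e-9)

    def test_small_displacement_tracks_nonlinear_transient(self, sp_model,
                                                           sp_steady):
        start = sp_steady.s_off + 0.05 * (sp_steady.s_on - sp_steady.s_off)
        ana = linearize(sp_model, sp_steady.s_off, 0.0,
                        displacement=start - sp_steady.s_off)
        traj = fb.integrate(sp_model, ConstantSignal(0.0, 40.0), start, 40.0)
        approx = deactivation_approximation(ana, traj.times)
        err = np.max(np.abs(approx - traj.output(0)))
        assert err < 0.10 * sp_steady.gap

    def test_no_feedback_reduction_collapses_to_closed_form(self):
        from fbnoise.models import closed_form_no_feedback

        params = {**fb.nominal_params("single_positive"), "k1": 0.0}
        model = fb.build_model("single_positive", params)
        y, _ = fb.integrate_to_stationarity(model, 0.0, np.array([0.3, 0.2]),
                                            tol=1e-11)
        start = y.copy()
        start[0] = 0.6
        ana = linearize(model, y, 0.0, displacement=start - y)
        t = np.linspace(0.0, 10.0, 50)
        assert np.max(np.abs(deactivation_approximation(ana, t)
                             - closed_form_no_feedback(params, 0.0, t,
                                                       C0=0.6))) < 1e-8


@pytest.fixture(scope="module")
def contributions():
    from fbnoise.studies import _loop_contribution

    def both(model_id, extra):
        nom = fb.nominal_params("single_positive")
        p = {**nom, "k5": nom["k1"], "k6": nom["k3"], "k7": nom["k4"],
             "b3": nom["b2"], **extra}
        model = fb.build_model(model_id, p if model_id != "single_positive"
                               else nom)
        ss = fb.compute_steady_states(model, 0.0, 1.0)
        return (_loop_contribution(model, ss, "act"),
                _loop_contribution(model, ss, "deact"))

    return {
        "sp": both("single_positive", {}),
        "ppss": both("positive_positive", {"tau_a": 5.0}),
        "ppfs": both("positive_positive", {"tau_a": 0.1}),
        "pnf": both("positive_negative", {"k5": 2.0, "tau_a": 0.1}),
        "pns": both("positive_negative", {"k5": 2.0, "tau_a": 5.0}),
    }


class TestContributionInequalities:
    def test_second_positive_loop_accelerates_activation(self, contributions):
        c = contributions
        assert c["ppss"][0] < c["sp"][0]
        assert c["ppfs"][0] < c["sp"][0]

    def test_slow_slow_loops_sustain_deactivation(self, contributions):
        c = contributions
        assert c["ppss"][1] > c["sp"][1]

    def test_fast_slow_deactivation_slightly_below_single(self, contributions):
        c = contributions
        ratio = c["ppfs"][1] / c["sp"][1]
        assert 0.6 < ratio < 1.0

    def test_negative_loop_effects(self, contributions):
        c = contributions
        assert c["pnf"][0] > c["sp"][0]   # fast negative loop slows activation
        assert c["pns"][0] < c["sp"][0]   # slow negative loop: slightly faster
        assert c["pnf"][1] > c["sp"][1]   # negative loop sustains deactivation

    def test_requires_displacement_and_stability(self, sp_model, sp_steady):
        ana = linearize(sp_model, sp_steady.s_on, 1.0)
        with pytest.raises(ValueError, match="displacement"):
            contribution_measure(ana)


class TestAnalyticQ:
    def test_scalar_filter_closed_form_to_1e10(self, linear_filter):
        from fbnoise.studies import scalar_filter_oracle_error

        assert scalar_filter_oracle_error() < 1e-10

    def test_fdt_monotone_in_association_and_time_scale(self):
        base = fb.nominal_params("single_positive")
        q0 = fdt_noise_amplification(base, 25.0).Q_analytic
        assert fdt_noise_amplification({**base, "k1": 2 * base["k1"]},
                                       25.0).Q_analytic < q0
        assert fdt_noise_amplification({**base, "tau": 2 * base["tau"]},
                                       25.0).Q_analytic < q0

    def test_fdt_regime_flags(self):
        base = fb.nominal_params("single_positive")
        res = fdt_noise_amplification(base, 0.2, delta=0.5)
        assert not res.in_regime  # slow, large noise: out of regime, flagged
        res2 = fdt_noise_amplification(base, 30.0, delta=0.1)
        assert res2.in_regime

    def test_oracle_Q_vanishes_at_high_frequency(self, sp_model, sp_steady):
        qs = [lyapunov_oracle_Q(sp_model, sp_steady.s_on, 1.0, 0.1, g)
              for g in (5.0, 20.0, 80.0, 320.0, 1280.0)]
        assert np.all(np.diff(qs) < 0)
        # white-noise regime: Q ~ gamma^(-1/2), so a 256x frequency increase
        # suppresses Q by ~16x
        assert qs[-1] < 0.1 * qs[0]

    def test_oracle_Q_amplitude_free(self, sp_model, sp_steady):
        q1 = lyapunov_oracle_Q(sp_model, sp_steady.s_on, 1.0, 0.05, 2.0)
        q2 = lyapunov_oracle_Q(sp_model, sp_steady.s_on, 1.0, 0.2, 2.0)
        assert q1 == pytest.approx(q2, rel=1e-10)

    def test_unstable_linearization_rejected(self, linear_filter):
        unstable = ModelSpec(
            model_id="user_plugin", state_names=("y",), output_index=0,
            params={}, rhs=lambda t, y, s: np.stack([y[..., 0]], axis=-1),
            box_lo=np.array([-np.inf]), box_hi=np.array([np.inf]),
            stimulus_jac=lambda y, s: np.array([1.0]))
        with pytest.raises(ValueError, match="stable"):
            lyapunov_oracle_Q(unstable, np.array([0.0]), 1.0, 0.1, 1.0)

    def test_three_routes_agree_in_regime(self, sp_model, sp_steady):
        """FDT closed form, exact propagator, and Monte-Carlo agree within
        20% pairwise in the small, fast-noise regime."""
        gamma, delta = 30.0, 0.1
        mc = fb.ensemble_Q(sp_model, 1.0, delta, gamma, n_reps=8, base_seed=1,
                           initial_state=sp_steady.s_on).mean_Q
        lyap = lyapunov_oracle_Q(sp_model, sp_steady.s_on, 1.0, delta, gamma)
        fdt = fdt_noise_amplification(sp_model.params, gamma, 1.0,
                                      delta).Q_analytic
        for a, b in [(mc, lyap), (mc, fdt), (lyap, fdt)]:
            assert abs(a - b) / min(a, b) < 0.2


class TestTwoTimescale:
    def test_fast_only_noise_filtered_exactly(self, sp_model, sp_steady):
        dur = 6.0
        fast = CenteredNoiseSignal(delta=0.3, gamma=20.0, duration=dur, seed=0)
        comp = CompositeSignal((ConstantSignal(1.0, dur), fast),
                               ("slow", "fast"), dur)
        zero = two_timescale_zero_order(sp_model, comp, sp_steady.s_on, dur)
        ref = fb.integrate(sp_model, ConstantSignal(1.0, dur), sp_steady.s_on,
                           dur)
        ref_at = np.interp(zero.times, ref.times, ref.output(0))
        assert np.max(np.abs(zero.output(0) - ref_at)) < 1e-9

    def test_epsilon_refinement_first_order(self, sp_model, sp_steady):
        errs = {}
        dur = 8.0
        for eps in (0.1, 0.05):
            fast = SquareWaveSignal(amplitude=0.3, period=eps, duration=dur)
            sig = CompositeSignal((ConstantSignal(1.0, dur), fast),
                                  ("slow", "fast"), dur)
            full = fb.integrate(sp_model, sig, sp_steady.s_on, dur,
                                rtol=1e-10, atol=1e-12)
            zero = two_timescale_zero_order(sp_model, sig, sp_steady.s_on,
                                            dur, rtol=1e-10, atol=1e-12)
            zi = np.interp(full.times, zero.times, zero.output(0))
            errs[eps] = np.max(np.abs(full.output(0) - zi))
        assert 1.5 < errs[0.1] / errs[0.05] < 3.0

    def test_constant_input_limit_matches_steady_state(self, sp_model,
                                                       sp_steady):
        dur = 120.0
        comp = CompositeSignal(
            (ConstantSignal(1.0, dur),
             SquareWaveSignal(amplitude=0.2, period=0.05, duration=dur)),
            ("slow", "fast"), dur)
        zero = two_timescale_zero_order(sp_model, comp, sp_model.box_lo, dur)
        assert zero.output(0)[-1] == pytest.approx(sp_steady.s_on[0],
                                                   abs=1e-4)

    def test_untagged_input_rejected(self, sp_model, sp_steady):
        with pytest.raises(TypeError):
            two_timescale_zero_order(sp_model, ConstantSignal(1.0, 5.0),
                                     sp_steady.s_on, 5.0)
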