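"""Model right-hand sides: schemas, fixed points, reductions, conservation."""

import numpy as np
import pytest

import fbnoise as fb
from fbnoise.models import (
    ConservationError,
    SchemaError,
    closed_form_no_feedback,
    hill,
    YEAST_L_HIGH,
    YEAST_L_LOW,
)

TOY_IDS = ["single_positive", "positive_positive", "positive_negative",
           "single_positive_hill", "positive_positive_hill"]
ALL_IDS = TOY_IDS + ["yeast_polarization", "polymyxin_fcl"]

ON_LEVEL = {mid: 1.0 for mid in ALL_IDS} | {"yeast_polarization": YEAST_L_HIGH}
OFF_LEVEL = {mid: 0.0 for mid in ALL_IDS} | {"yeast_polarization": YEAST_L_LOW}


class TestSchema:
    def test_missing_parameter_rejected(self):
        params = fb.nominal_params("single_positive")
        params.pop("k3")
        with pytest.raises(SchemaError, match="k3"):
            fb.build_model("single_positive", params)

    def test_unknown_parameter_rejected_with_hint(self):
        with pytest.raises(SchemaError, match="k1"):
            fb.build_model("single_positive",
                           {**fb.nominal_params("single_positive"), "k1x": 1.0})

    def test_negative_rate_rejected(self):
        with pytest.raises(SchemaError, match="k2"):
            fb.build_model("single_positive", k2=-0.5)

    def test_nonpositive_time_scale_rejected(self):
        with pytest.raises(SchemaError, match="tau"):
            fb.build_model("single_positive", tau=0.0)

    def test_hill_coefficient_below_one_rejected(self):
        with pytest.raises(SchemaError, match="nB"):
            fb.build_model("single_positive_hill", nB=0.5)

    def test_nonpositive_half_saturation_rejected(self):
        with pytest.raises(SchemaError, match="KB"):
            fb.build_model("single_positive_hill", KB=0.0)

    def test_unknown_model_id(self):
        with pytest.raises(KeyError):
            fb.build_model("triple_positive")


class TestRhsContracts:
    @pytest.mark.parametrize("model_id", ALL_IDS)
    def test_fixed_points_annihilate_rhs(self, model_id):
        model = fb.build_model(model_id)
        ss = fb.compute_steady_states(model, OFF_LEVEL[model_id],
                                      ON_LEVEL[model_id])
        for state, level in [(ss.s_off, OFF_LEVEL[model_id]),
                             (ss.s_on, ON_LEVEL[model_id])]:
            assert np.max(np.abs(model.rhs(0.0, state, level))) < 1e-10

    @pytest.mark.parametrize("model_id", TOY_IDS)
    def test_boundary_derivatives_point_inward(self, model_id):
        """At a normalized coordinate pinned to 1 with positive deactivation,
        that coordinate cannot increase further (sign analysis of each term,
        verified over a parameter grid)."""
        rng = np.random.default_rng(0)
        nominal = fb.nominal_params(model_id)
        for _ in range(25):
            params = {k: (v * rng.uniform(0.5, 2.0) if k[0] in "kb" else v)
                      for k, v in nominal.items()}
            model = fb.build_model(model_id, params)
            for i in range(model.state_dim):
                y = rng.uniform(0.0, 1.0, model.state_dim)
                y[i] = 1.0
                dy = model.rhs(0.0, y, rng.uniform(0.0, 2.0))
                assert dy[i] <= 1e-12
                y[i] = 0.0
                dy = model.rhs(0.0, y, rng.uniform(0.0, 2.0))
                assert dy[i] >= -1e-12

    def test_nan_state_rejected(self, sp_model):
        with pytest.raises(ValueError, match="NaN"):
            sp_model(0.0, np.array([np.nan, 0.5]), 1.0)

    def test_negative_stimulus_rejected(self, sp_model):
        with pytest.raises(ValueError, match="nonnegative"):
            sp_model(0.0, np.array([0.5, 0.5]), -0.1)

    def test_vectorized_rhs_matches_loop(self, sp_model):
        rng = np.random.default_rng(1)
        ys = rng.uniform(0, 1, (7, 2))
        batch = sp_model.rhs(0.0, ys, 0.8)
        single = np.array([sp_model.rhs(0.0, y, 0.8) for y in ys])
        assert np.allclose(batch, single, atol=1e-14)


class TestReductions:
    @pytest.mark.parametrize("model_id", ["positive_positive", "positive_negative"])
    def test_zeroed_second_loop_reduces_to_single_positive(self, model_id):
        sp = fb.build_model("single_positive")
        reduced = fb.build_model(model_id, {**fb.nominal_params(model_id),
                                            "k5": 0.0, "k6": 0.0, "b3": 0.0})
        sig = fb.make_step_signal(1.0, 0.0, 10.0, 30.0)
        t1 = fb.integrate(sp, sig, np.array([0.5, 0.5]), 30.0,
                          rtol=1e-11, atol=1e-13)
        t2 = fb.integrate(reduced, sig, np.array([0.5, 0.5, 0.0]), 30.0,
                          rtol=1e-11, atol=1e-13)
        c = np.interp(t1.times, t2.times, t2.states[:, 0])
        b = np.interp(t1.times, t2.times, t2.states[:, 1])
        assert np.max(np.abs(t1.states[:, 0] - c)) < 1e-8
        assert np.max(np.abs(t1.states[:, 1] - b)) < 1e-8

    def test_positive_positive_loop_swap_symmetry(self):
        base = fb.nominal_params("positive_positive")
        p1 = {**base, "k1": 7.0, "k3": 9.0, "k4": 0.8, "b2": 0.002, "tau": 4.0,
              "k5": 11.0, "k6": 12.0, "k7": 1.2, "b3": 0.003, "tau_a": 0.7}
        p2 = {**base, "k5": 7.0, "k6": 9.0, "k7": 0.8, "b3": 0.002,
              "tau_a": 4.0, "k1": 11.0, "k3": 12.0, "k4": 1.2, "b2": 0.003,
              "tau": 0.7}
        m1 = fb.build_model("positive_positive", p1)
        m2 = fb.build_model("positive_positive", p2)
        sig = fb.make_step_signal(0.0, 1.0, 5.0, 25.0)
        t1 = fb.integrate(m1, sig, np.array([0.1, 0.2, 0.3]), 25.0,
                          rtol=1e-11, atol=1e-13)
        t2 = fb.integrate(m2, sig, np.array([0.1, 0.3, 0.2]), 25.0,
                          rtol=1e-11, atol=1e-13)
        out2 = np.interp(t1.times, t2.times, t2.output(0))
        assert np.max(np.abs(t1.output(0) - out2)) < 1e-9

    def test_stronger_negative_feedback_lowers_active_output(self):
        levels = []
        for k5 in [0.5, 1.0, 2.0, 4.0]:
            m = fb.build_model("positive_negative", k5=k5)
            ss = fb.compute_steady_states(m, 0.0, 1.0)
            levels.append(ss.s_on[0])
        assert np.all(np.diff(levels) < 0)


class TestHill:
    def test_half_saturation_identity(self):
        assert hill(0.3, 0.3, 2.0) == pytest.approx(0.5)
        assert hill(0.3, 0.3, 7.0) == pytest.approx(0.5)

    def test_low_occupancy_limit_matches_mass_action(self):
        """Hill coefficient 1 with large half-saturation (rates rescaled by K)
        reproduces the bilinear model to ~B/K relative accuracy."""
        base = fb.nominal_params("single_positive")
        K = 50.0
        ph = {**fb.nominal_params("single_positive_hill"),
              "k1": base["k1"] * K, "KB": K, "nB": 1.0,
              "k3": base["k3"] * K, "KC": K, "nC": 1.0}
        mh = fb.build_model("single_positive_hill", ph)
        ma = fb.build_model("single_positive", base)
        sig = fb.make_step_signal(0.0, 1.0, 5.0, 30.0)
        y0 = np.array([0.02, 0.001])
        t1 = fb.integrate(ma, sig, y0, 30.0)
        t2 = fb.integrate(mh, sig, y0, 30.0)
        out2 = np.interp(t1.times, t2.times, t2.output(0))
        rel = np.max(np.abs(t1.output(0) - out2)) / np.max(t1.output(0))
        assert rel < 0.02


class TestYeast:
    def test_conservation_pools_nonnegative_and_constant(self):
        model = fb.build_model("yeast_polarization")
        ss = fb.compute_steady_states(model, YEAST_L_LOW, YEAST_L_HIGH)
        sig = fb.make_noisy_signal(YEAST_L_HIGH, 0.6, 1.0, 30.0, seed=3)
        traj = fb.integrate(model, sig, ss.s_on, 30.0)
        derived = model.derived_species(traj.states)
        for name, vals in derived.items():
            assert np.min(vals) >= -1e-9, name
        # pool totals are identities of the derived construction: verify the
        # G-protein bookkeeping explicitly along the trajectory
        G = derived["G"]
        Gd = derived["Gd"]
        Ga = traj.states[:, 1]
        total = G + Ga + Gd
        assert np.max(np.abs(total - total[0])) < 1e-6

    def test_conservation_violation_raises(self):
        model = fb.build_model("yeast_polarization")
        bad = model.box_lo.copy()
        bad[1] = 0.5  # Ga above Gbg makes derived Gd negative
        with pytest.raises(ConservationError):
            model.derived_species(bad)

    def test_zero_ligand_stays_inactive(self):
        model = fb.build_model("yeast_polarization")
        traj = fb.integrate(model, fb.ConstantSignal(0.0, 50.0), model.box_lo,
                            50.0)
        assert traj.output(4).max() < 1e-6
        terminus, _ = fb.integrate_to_stationarity(model, 0.0, model.box_lo)
        assert np.max(np.abs(model.rhs(0.0, terminus, 0.0))) < 1e-9

    def test_high_vs_low_pheromone_distinguishable_outputs(self):
        model = fb.build_model("yeast_polarization")
        ss = fb.compute_steady_states(model, YEAST_L_LOW, YEAST_L_HIGH)
        assert ss.s_on[4] > 5 * ss.s_off[4]
        assert ss.s_on[4] > 0.5


class TestPolymyxinFCL:
    def test_fast_activation_slow_deactivation(self):
        model = fb.build_model("polymyxin_fcl")
        ts = fb.measure_timescales(model, 0.0, 1.0, gamma=1.0)
        assert ts.t_act < ts.t_deact

    def test_doubling_mrna_degradation_shortens_deactivation(self):
        base = fb.nominal_params("polymyxin_fcl")
        t1 = fb.measure_timescales(fb.build_model("polymyxin_fcl", base),
                                   0.0, 1.0, 1.0).t_deact
        t2 = fb.measure_timescales(
            fb.build_model("polymyxin_fcl", {**base, "d5": 2 * base["d5"]}),
            0.0, 1.0, 1.0).t_deact
        assert t2 < t1

    def test_pmra_pool_conserved(self):
        model = fb.build_model("polymyxin_fcl")
        ss = fb.compute_steady_states(model, 0.0, 1.0)
        derived = model.derived_species(ss.s_on)
        assert derived["PmrA"] >= 0
        total = ss.s_on[2] + ss.s_on[3] + derived["PmrA"]
        assert total == pytest.approx(model.params["At"], abs=1e-9)


class TestClosedForm:
    def test_initial_condition_and_limit(self):
        params = {**fb.nominal_params("single_positive"), "k1": 0.0}
        assert closed_form_no_feedback(params, 0.0, 0.0, C0=0.9) == pytest.approx(0.9)
        b1, k2 = params["b1"], params["k2"]
        assert closed_form_no_feedback(params, 0.0, 1e9, C0=0.9) == \
            pytest.approx(b1 / (b1 + k2))

    def test_matches_integrator_to_1e6(self):
        params = {**fb.nominal_params("single_positive"), "k1": 0.0}
        model = fb.build_model("single_positive", params)
        traj = fb.integrate(model, fb.ConstantSignal(0.0, 25.0),
                            np.array([0.9, 0.5]), 20.0, rtol=1e-11, atol=1e-13)
        times = np.linspace(0.0, 20.0, 20)
        num = np.interp(times, traj.times, traj.output(0))
        ana = closed_form_no_feedback(params, 0.0, times, C0=0.9)
        assert np.max(np.abs(num - ana)) < 1e-6

    def test_requires_zero_feedback(self):
        with pytest.raises(ValueError, match="k1"):
            closed_form_no_feedback(fb.nominal_params("single_positive"),
                                    0.0, 1.0)


class TestPlugins:
    def test_register_and_build_plugin(self, linear_filter):
        from fbnoise.models import register_model, _BUILDERS

        def builder(params):
            return linear_filter

        register_model("my_filter", builder, {"tau_f": 2.0})
        try:
            m = fb.build_model("my_filter")
            assert m.state_dim == 1
            with pytest.raises(ValueError):
                register_model("my_filter", builder, {})
        finally:
            _BUILDERS.pop("my_filter", None)
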