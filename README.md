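# fbnoise

Noise attenuation in feedback circuits: how well does a signalling module,
held in its active state by a stimulus, suppress temporal noise in that
stimulus?

`fbnoise` simulates small input-output feedback ODE modules — a
single-positive-loop switch, two-positive-loop and positive-negative-loop
variants, saturating (Hill) versions, a non-spatial yeast pheromone
polarization pathway, and a polymyxin-B resistance connector circuit —
under piecewise-constant uniform input noise, and quantifies two things:

* the **signed activation time** of the noise-free system,

  `T = gamma * (t_deact - t_act)`,

  the difference between the deactivation and activation time scales
  counted in periods of the input noise (frequency `gamma`); and

* the **noise amplification rate** at the active state,

  `Q = CV(output) / CV(input)`,

  the ratio of the coefficients of variation over a stationary window.

Across every circuit in the package, Q decreases monotonically in T: fast
activation combined with slow deactivation is what makes a feedback module
a good noise filter, regardless of the sign or number of its loops.  The
package verifies this numerically (seeded parameter and frequency sweeps
with Spearman trend statistics) and analytically (linear stability and mode
contribution measures, a fluctuation-dissipation closed form for Q, an
exact propagator/Lyapunov oracle, and a two-time-scale expansion showing
the modules act as low-pass filters).  See `docs/methods.md` for the models
and estimators in detail.

It is intended for computational/systems biologists studying feedback
design principles, and as a reference implementation of the signed
activation time diagnostic.

## Worked example

```python
import fbnoise as fb

model = fb.build_model("single_positive")           # nominal kinetic set
steady = fb.compute_steady_states(model, S_low=0.0, S_high=1.0)
ts = fb.measure_timescales(model, 0.0, 1.0, gamma=1.0)
ens = fb.ensemble_Q(model, S0=1.0, delta=0.3, gamma=1.0,
                    n_reps=20, base_seed=1, initial_state=steady.s_on,
                    s_off_output=float(steady.s_off[0]))

print(f"inactive output C_off = {steady.s_off[0]:.4f}, "
      f"active output C_on = {steady.s_on[0]:.4f}")
print(f"t_act = {ts.t_act:.3f}, t_deact = {ts.t_deact:.3f}, T = {ts.T:.3f}")
print(f"Q = {ens.mean_Q:.5f} +/- {ens.sem_Q:.5f}")
```

prints

```
inactive output C_off = 0.0196, active output C_on = 0.9001
t_act = 1.632, t_deact = 23.398, T = 21.766
Q = 0.00771 +/- 0.00003
```

The switch sits at ~0.02 when the stimulus is low and ~0.90 when it is
high.  It activates in ~1.6 time units but needs ~23 to deactivate, so with
noise of unit frequency the signed activation time is ~22 noise periods —
deep in the noise-attenuating regime — and input fluctuations with a 17%
coefficient of variation (`delta/(sqrt(3)*S0)`) are suppressed to a 0.13%
output CV, i.e. Q ≈ 0.008.  Slowing the loop or weakening the feedback
shrinks T and raises Q; a sweep makes the inverse relation explicit:

```python
noise = fb.NoiseSpec(S0=1.0, delta=0.3, gamma=1.0)
grid = fb.geometric_grid(10.0, 2.0, 10)             # k1 from 5 to 20
points = fb.sweep_parameter("single_positive", "k1", grid, noise,
                            n_reps=20, base_seed=0)
print(fb.trend_test(points, threshold=-0.9))        # rho = -1.0, passed
```

## Command line

Every protocol is also a `fbnoise` subcommand emitting JSON/CSV artifacts
plus a resolved-configuration sidecar:

```sh
fbnoise timescales --model single_positive --gamma 1.0 --out results/
fbnoise sweep --model single_positive --param k1 --n-reps 20 --seed 1 --out results/
fbnoise fixtures          # list packaged model/noise fixture configs
```

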