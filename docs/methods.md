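# Methods

This note documents the models, estimators, and numerical choices behind
`fbnoise`, and what its synthetic studies do and do not establish.

## The question the package addresses

A signalling module held in its active ("on") state by a stimulus receives
that stimulus with temporal noise.  How strongly do the input fluctuations
propagate to the output?  The package's central diagnostic is the **signed
activation time**

    T = gamma * (t_deact - t_act)

where `t_act` and `t_deact` are the activation and deactivation time scales
of the *noise-free* system and `gamma` is the input-noise frequency.  The
quantity it predicts is the **noise amplification rate**

    Q = CV(output) / CV(input)

measured over a stationary window at the on state.  Across every circuit in
the package, Q decreases monotonically in T: a system that deactivates
slowly (it takes long to "believe" a downward excursion of the stimulus)
and activates fast (it recovers quickly afterwards) is a good noise filter.

## Feedback modules

All toy modules use normalized active fractions in [0, 1] and mass-action
kinetics.  The single-positive-loop module has an output `C` and a loop
species `B`:

    dC/dt = (k1*B + b1)(1 - C) - k2*C
    tau * dB/dt = (k3*S(t)*C + b2)(1 - B) - k4*B

The stimulus activates the loop *together with* the output (`S*C`), which is
the positive feedback; `k1` and `k3` are the two association constants, `k2`
and `k4` the deactivation rates, `b1`, `b2` small basal activations, and
`tau` the loop time scale (large `tau` = slow loop).  Nominal values
(`k1 = k3 = 10`, `k2 = k4 = 1`, `b1 = 0.01`, `b2 = 0.001`, `tau = 5`) place
the module in the switch-like regime: output ~0.02 at `S = 0`, ~0.90 at
`S = 1`, with fast activation (t_act ≈ 1.6) and slow deactivation
(t_deact ≈ 23) at the 90%-traversal threshold.

The two-loop variants add a species `A` with its own couplings
(`k5, k6, k7, b3, tau_a`): activating the output in `positive_positive`
(symmetric with loop `B`), deactivating it (`-k5*A*C`) in
`positive_negative`.  `tau_a` selects the regime: `tau_a << tau` is the
fast-slow (dual-time) configuration, `tau_a = tau` slow-slow.  The
positive-negative nominal uses the slow regime, where the negative-loop
couplings move T appreciably.  Hill variants replace the bilinear
association terms with `x^n/(K^n + x^n)`; with cooperative exponents
(n = 2) they are bistable over a window of stimulus levels, which the
mass-action module with these basal rates is not.

Two literature-scale circuits exercise the same pipeline: a non-spatial
yeast pheromone polarization pathway (receptor/G-protein cycle, Cdc24/Bem1
positive loop gated by free G-beta-gamma, Cla4 negative loop; output active
Cdc42; conservation pools close the heterotrimeric G-protein, Cdc42, Cdc24,
Bem1 and Cla4 totals, with a membrane/cytoplasm scale factor `rho`), and a
five-variable polymyxin-B resistance connector circuit (input
phospho-PhoP, output pbgP mRNA) in which the connector protein PmrD binds
and protects phosphorylated PmrA from dephosphorylation; the slow
dissociation of the protected complex produces the circuit's hallmark slow
deactivation, while a direct (feedforward) input arm on the pbgP promoter
speeds activation.  Parameter values for both are package choices placed in
the biologically sensible operating regime (clearly separated on/off
states; mild basal PmrA phosphorylation so that protection, not
phosphorylation, forms the switch); concentrations are normalized to pool
totals and time is measured in units of the receptor (respectively mRNA)
turnover time.

## Stimulus noise

Noise is extrinsic and piecewise-constant: time is divided into segments of
length `1/gamma` and each segment holds an independent draw from
`U[S0 - delta, S0 + delta]` (CV = `delta/(sqrt(3)*S0)`).  Segments are
right-open and signals right-continuous, so integrators restart cleanly at
the known breakpoints.  Signals are pure functions of their parameters and
an integer seed; replicate k of an ensemble uses `seed + k`.  Negative
stimulus values are rejected at construction, never clipped.  Zero-mean
fluctuation components (centered uniform noise, square waves) exist for the
two-time-scale machinery and are only admissible inside composites whose
sum stays nonnegative.

## Time-scale measurement

`t_act` (`t_deact`) is the first time the output, started at the inactive
(active) stationary state under the stepped stimulus, traverses a fraction
`theta` of the stationary output gap.  `theta = 0.9` by default: the
schematic definition of the response time is a traversal criterion, and 90%
matches the `tau*ln 10` intuition for exponential relaxation while being
robust to overshoot; first crossings count, re-crossings are ignored (all
built-in step responses are monotone near threshold).  Stationary states
are found by relaxation followed by a damped Newton polish to residual
`< 1e-10`; in a bistable window the relaxation path (off reached from the
box floor at `S_low`, on reached from off at `S_high`) selects the branches
a step protocol actually visits.

Because "normalized by the noise frequency" admits two readings, the
normalization is pluggable: `T = gamma*(t_deact - t_act)` (default, the
time-scale difference counted in noise periods) or the difference divided
by `gamma`.  All shipped studies use the default.

## Noise amplification estimation

Runs start *at* the active stationary state.  Burn-in discards
`max(10/gamma, 8/|Re lambda|_min)` (slowest linearized relaxation time at
the on state), after which CVs are estimated over 1000 noise periods
(500 for the yeast circuit) sampled
~16-20 times per period.  The input CV in the denominator is computed from
the realized sampled input on the same grid, so numerator and denominator
see the same finite realization.  Replicates whose median output falls
below the midpoint between the on and off output levels are flagged as
state flips and excluded from ensemble means (they are a qualitative
failure mode, not a variance contribution); flip counts are reported.

Ensembles integrate with a fixed-step classical RK4 sweep, vectorized over
replicates, stepping `max(8, ceil(1.2 * |lambda|_max / gamma))` sub-steps
per noise segment (stability plus accuracy headroom for the fastest local
rate); within a segment the right-hand side is smooth, so RK4's fourth-order
accuracy applies segmentwise.  The sweep is cross-checked in the test suite
against the adaptive segment-restarting integrator on identical noise
realizations (agreement ~1e-5 sup-norm over 30 periods).

## Linear analysis and contribution measures

At a stationary state the Jacobian (analytic for the mass-action toys,
central finite differences with step `max(1e-6, 1e-6*|x|)` otherwise) is
eigendecomposed; eigenvalues are ordered by ascending `|Re|` with ties
broken by imaginary part then index.  A step transient's initial
displacement is expanded on the eigenbasis, giving the linearized output
transient `sum_i c_i v_i[out] exp(lambda_i t)`.

The **loop contribution measure** summarizes how much of a transient the
feedback loops carry: the eigenmode whose unit eigenvector lies most along
the output coordinate is taken as the output's own relaxation, and the
measure is the time-integrated magnitude of all other modes' output terms,
normalized by the stationary gap: `sum_{i != out} |c_i v_i[out] /
Re lambda_i| / gap`.  Matched comparisons of this number reproduce, with
zero violations over 200 randomized parameter sets per regime, the
qualitative algebra of the architectures: a second positive loop (slow-slow
or genuinely fast, `tau_a` in [0.05, 0.2] against `tau` in [4, 8]) shrinks
the activation contribution; slow-slow loops enlarge the deactivation
contribution while a fast second loop shrinks it only slightly (ratio in
(0.86, 0.97) across the sampled regimes); a fast negative loop enlarges
both; a slow negative loop slightly shrinks the activation contribution.
The regimes matter: a "fast" second loop whose rate is comparable to the
output's own relaxation behaves like a slow one, and the fast-slow
inequalities do not apply to it.

## Analytic noise amplification

Two analytic routes complement the simulations:

* **Fluctuation-dissipation closed form** (single-positive module): in the
  white-noise limit of the piecewise-constant input (noise faster than
  every mode), the stationary output variance of the linearized 2x2 system
  is `sigma^2 * Delta * (J01 * g)^2 / (-2 tr(J) det(J))` with `g` the
  stimulus sensitivity of the loop equation, giving an amplitude-free Q
  proportional to `1/sqrt(gamma)`.  Under the package's time-scale
  convention this Q decreases in the association constant `k1` and in the
  loop time scale `tau`, while T increases in both — the inverse relation
  in analytic form.  Validity flags record small noise (`delta/S0 <= 0.2`),
  fast noise (`|Re lambda|_max / gamma <= 0.5`) and stability;
  out-of-regime evaluation returns a flagged value rather than refusing.

* **Exact propagator oracle** (any module): over one noise segment the
  linearized deviation obeys `x_{n+1} = F x_n + h eta_n` with
  `F = exp(J/gamma)`, `h = J^{-1}(F - I) g`; the stationary segment-start
  covariance is the discrete Lyapunov fixed point and the within-segment
  time average is evaluated exactly via continuous Lyapunov identities.
  For the scalar first-order filter this reproduces the hand-derived
  closed form to ~1e-11, and it agrees with the closed form above and with
  Monte-Carlo estimates within a few percent in regime.

## Two-time-scale expansion

For an input declared as a sum of slow and fast components (tags are
explicit; no scale inference), the zero-order slow equation is the model
driven by the slow part alone — fast input fluctuations are absent from it
by construction, which is the analytic statement that these modules act as
low-pass filters.  The identity check (zero-order solution with fast noise
equals the noise-free solution) is exact.  The convergence-rate study uses
a deterministic zero-mean square wave as the fast component: for such
bounded-integral fast inputs the full-minus-zero-order error is O(eps)
(eps = fast period), and halving eps halves the error (observed ratio
~1.9); a random fast component instead gives the O(sqrt(eps)) rate of
stochastic averaging and is not used for the rate check.

## Sweep studies

Each sweep varies one parameter on a 10-point geometric grid spanning a
2-fold range either side of nominal (fold ranges are package choices;
grids are geometric because the parameters are rates), holding the noise
conditions fixed (`S0 = 1, delta = 0.3, gamma = 1` for the toys; pheromone
`2.0 +/- 0.6` for the yeast circuit), and runs 20 noisy replicates per
point for the single-positive module (10 for the other toys and the
connector circuit, 3 for the yeast circuit — the larger models are costlier
and their trends wider).  The trend statistic is the Spearman rank
correlation between mean Q and T; the shipped studies yield rho <= -0.9
for every single-positive parameter and frequency sweep and rho <= -0.8
(typically <= -0.9) for every sweep of every other architecture.  For the
connector circuit, the ten swept parameters are the upstream
(switch-forming) ones; the three output-transcription parameters
(`a5, K5, d5`) rescale the reporter and set its bandwidth without moving
the circuit's switching times, so they move Q while leaving T nearly
unchanged and carry no information about the T-Q relation.  The yeast
sweep set is chosen by the same principle: the direct
G-beta-gamma-to-Cdc24 recruitment rate (`k24g`) transmits input
fluctuations to the output without passing through the Bem1 latch, so its
effect on Q is direct-transmission-dominated and it is excluded in favor
of the receptor turnover rate (`kRLm`).

## What the synthetic studies do not show

The generator produces uniform, piecewise-constant, purely extrinsic input
noise; real signalling noise has continuous spectra, intrinsic (copy-number)
components, and output measurement error, none of which are modeled.  The
yeast circuit is deliberately non-spatial; parameter values for both
literature-scale circuits are reconstructions placed in the qualitative
operating regime rather than fitted values, so their absolute time scales
and Q values are illustrative.  Passing studies establish the inverse Q-T
relationship and the architecture comparisons within these model classes,
not quantitative predictions for any particular organism.

## Numerical choices and degenerate inputs

Adaptive integration uses RK45 (LSODA for the stiff literature circuits) at
rtol 1e-8 / atol 1e-10, restarted at every input breakpoint; halving the
tolerances moves fixture outputs by < 1e-6.  Crossing times are located by
a terminal event plus a Brent polish on the dense output.  States are
admissibility-checked against each model's box with 1e-9 slack, and
conservation pools reject derived concentrations below -1e-9.  Degenerate
inputs fail loudly: negative stimulus values, NaN states, unknown or
out-of-range parameters (with closest-match hints), untagged composites,
zero-mean series in a CV, stimulus levels that do not separate the on/off
states.  Non-convergent stationarity searches return a flag, not an
exception; per-point sweep failures are recorded in the table rather than
aborting the sweep.
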