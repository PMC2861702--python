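model:
  id: single_positive_hill
  params:
    k1: 10.0
    k2: 1.0
    k3: 10.0
    k4: 1.0
    b1: 0.01
    b2: 0.001
    tau: 5.0
    KB: 0.3
    nB: 2.0
    KC: 0.3
    nC: 2.0
noise:
  S0: 1.0
  delta: 0.3
  gamma: 1.0
  S_low: 0.0
sweep_params:
- k1
- k2
- k3
- k4
fold: 2.0
n_reps: 10
window_periods: 1000
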