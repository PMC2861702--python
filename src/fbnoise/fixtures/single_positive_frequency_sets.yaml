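model:
  id: single_positive
noise:
  S0: 1.0
  delta: 0.3
  gamma: 1.0
  S_low: 0.0
gamma_grid:
- 0.2
- 0.32
- 0.5
- 0.79
- 1.26
- 2.0
- 3.2
- 5.0
sets:
  set1: {}
  set2:
    k1: 5.0
    k3: 5.0
  set3:
    tau: 10.0
  set4:
    k2: 2.0
    k4: 0.5
n_reps: 20
window_periods: 1000
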