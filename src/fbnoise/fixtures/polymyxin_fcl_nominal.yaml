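model:
  id: polymyxin_fcl
  params:
    a1: 2.0
    K1: 0.5
    d1: 1.0
    t2: 0.5
    d2: 0.5
    kph: 0.05
    kdeph: 2.0
    At: 1.0
    kon: 1.0
    koff: 0.02
    a5: 2.0
    K5: 0.2
    d5: 0.3
noise:
  S0: 1.0
  delta: 0.3
  gamma: 1.0
  S_low: 0.0
sweep_params:
- a1
- K1
- d1
- t2
- d2
- kph
- kdeph
- At
- kon
- koff
fold: 2.0
n_reps: 10
window_periods: 1000
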