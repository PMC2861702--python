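model:
  id: yeast_polarization
  params:
    kRL: 1.0
    kRLm: 1.0
    Rt: 1.0
    kGa: 2.0
    kGd: 1.0
    kG1: 5.0
    Gt: 1.0
    k24g: 0.2
    K1: 0.5
    q1: 4.0
    kB24: 4.0
    k24m: 1.0
    kCla: 1.0
    C24t: 1.0
    k42: 6.0
    k42m: 1.0
    C42t: 1.0
    kB1: 6.0
    K2: 0.5
    q2: 4.0
    kB1m: 1.0
    B1t: 1.0
    kCla4: 1.0
    kCla4m: 2.0
    Cla4t: 1.0
    rho: 1.0
noise:
  S0: 2.0
  delta: 0.6
  gamma: 1.0
  S_low: 0.01
sweep_params:
- k42
- k42m
- kRLm
- k24m
- kB24
- kB1
- kB1m
- kCla
- kGa
- kGd
fold: 2.0
n_reps: 3
window_periods: 500
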