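Q: 10
dt: 1.0
n_steps: 100000
initial: uniform
enabled:
- ff_metabolic
- ff_protein
- mb
- repair
- ec
- ed
seed: 0
record_every: 100
record_snapshots: false
params:
  gamma: 1.0
  ff1: 2.0
  ff2: 3.0
  f_rd: 0.03
  laws:
    ffm:
      rho0: 0.05
      tau: 50000.0
      direction: decay
      cap: false
    ffp_fusion:
      rho0: 0.05
      tau: 50000.0
      direction: decay
      cap: false
    ffp_fission:
      rho0: 0.05
      tau: 50000.0
      direction: growth
      cap: false
    mb:
      rho0: 0.01
      tau: 50000.0
      direction: growth
      cap: false
    rep:
      rho0: 0.01
      tau: 50000.0
      direction: decay
      cap: false
    ec:
      rho0: 0.05
      tau: 50000.0
      direction: growth
      cap: false
    ed:
      rho0: 0.01
      tau: 50000.0
      direction: growth
      cap: false
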