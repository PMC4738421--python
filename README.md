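# mitoq

A fully time-dependent master-equation model of mitochondrial quality
during cell aging.

## The problem

Mitochondria keep eukaryotic cells supplied with ATP, and their ability to
do so degrades as cells age: fission/fusion cycles slow down, mitophagy
increases, repair of mtDNA damage declines, and reactive oxygen species
(ROS) — both self-generated and external — accumulate damage.  `mitoq`
models a mitochondrion's state as a discrete quality level
*q* ∈ {0, …, *Q*} (*q* = 0 is the inactive, membrane-depolarized state)
occupied with probability *P*(*q*, *t*), normalized so that
∑<sub>q</sub> *P*(*q*, *t*) = 1.  The population evolves under a master
equation whose right-hand side is a sum of five process terms:

∂P/∂t = ∂P_FF + ∂P_MB + ∂P_REP + ∂P_EC + ∂P_ED

* **FF — fission/fusion (networking)**: a metabolic "kiss-and-run" part
  that mixes two active mitochondria to their average quality (conserving
  total quality), and a proteinaceous part in which fusion raises the
  lower partner to the higher quality while fission sends one member of a
  like-quality pair to the inactive state.  Exchange rates follow a Hill
  law in the quality difference, Δ^FF1 / (FF2^FF1 + Δ^FF1).
* **MB — mitophagy/biogenesis (recycling)**: coupled removal of
  inactive-state probability and creation at the top quality *Q*.
* **REP — repair**: each missing quality unit is independently restored
  with probability ρ_rep(*t*) (a binomial kernel).
* **EC — energy consumption**: activity-dependent internal ROS damage;
  each of a state's *q* quality units is lost with probability ρ_ec(*t*)
  (the mirrored binomial kernel), so active mitochondria damage
  themselves more.
* **ED — external damage**: a stochastic map, gated per time step with
  probability ρ_ed(*t*), that moves a fraction *f*_rd of a random higher
  state's mass to a random lower state.

Every process *i* carries an exponential time law
ρ<sub>i</sub>(*t*) = ρ<sub>0,i</sub>·exp(±*t*/τ<sub>i</sub>) describing
how its intensity decays or grows as the cell ages; setting
τ<sub>i</sub> = 5·10⁸ tu freezes a process ("non-aging").  The equation is
integrated with explicit Euler steps (Δt = 1 tu) under a strict
probability-conservation guard (*N*_prob = 1 to 12 decimals at every
step).  Reported metrics are the average quality q̄ = ∑ q·P(q,t), the
mean absolute deviation σ_q = ∑ |q − q̄|·P(q,t), and the inactive
fraction *P*(0, *t*), a proxy for fragmentation of the mitochondrial
network.

## Worked example

Every simulation experiment ships as a named preset
(`mitoq.scenario_names()` lists them).  Comparing networking, recycling,
and their interplay over 30000 tu from a uniform start:

```python
from mitoq import build_scenario, run_simulation

for name in ["ff_metabolic_only", "ff_protein_only", "single_ff",
             "single_mb", "interplay"]:
    m = run_simulation(build_scenario(name).config).final_metrics
    print(f"{name:18s} qbar={m.qbar:6.3f}  sigma_q={m.sigma_q:6.3f}  P(0)={m.p0:6.3f}")
```

```
ff_metabolic_only  qbar= 5.000  sigma_q= 0.909  P(0)= 0.091
ff_protein_only    qbar= 7.448  sigma_q= 3.801  P(0)= 0.255
single_ff          qbar= 5.662  sigma_q= 4.912  P(0)= 0.434
single_mb          qbar= 5.909  sigma_q= 2.645  P(0)= 0.000
interplay          qbar=10.000  sigma_q= 0.000  P(0)= 0.000
```

Metabolic mixing narrows the distribution without moving its mean;
proteinaceous networking raises quality but feeds the inactive state;
combined fission/fusion settles into a polarized state with 43% inactive
mitochondria; recycling alone stalls once the inactive pool is empty.
Their interplay, however, pumps the entire population to the maximal
quality — fission keeps supplying inactive mitochondria for mitophagy,
and the coupled biogenesis re-creates them at top quality.

The `examples/` directory contains one narrative script per capability
(single processes, networking vs recycling, aging vs non-aging and stable
repair, high-energy-demand rescue strategies, config-file round trips),
and `mitoq simulate --scenario aging --seed 42 --out run/` runs any
preset from the shell, writing `metrics.csv`, optional `snapshots.csv`,
and a reproducibility manifest.

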