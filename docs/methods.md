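# Methods

## Model

A mitochondrion's condition — metabolite supply, respiratory activity,
mtDNA/protein integrity — is collapsed into one discrete quality state
q ∈ {0, …, Q} with occupation probabilities P(q, t), ∑ P = 1.  The default
Q = 10 (11 states); the process balance is supported for 5–15 states
(Q = 4–14), enforced by the configuration validator.  q = 0 is the
inactive state: membrane-depolarized, excluded from networking, waiting
for repair or mitophagy.

The master equation dP/dt = R(t)·P is never built as an explicit
transition matrix; each of the five processes contributes its
probability-change vector directly:

### Time laws

Every process i has intensity ρ_i(t) = ρ0_i · exp(±t/τ_i) with starting
probability ρ0_i ∈ [0, 1] and lifetime τ_i > 0 (time unit "tu"; one Euler
step is Δt = 1 tu).  Networking and repair decay with age; mitophagy,
internal and external damage, and proteinaceous fission grow.  A process
is frozen in time by the conventional lifetime τ = 5·10⁸ tu (an exact
`constant` mode also exists and is used in property tests; presets use
the 5·10⁸ convention).  A law that leaves [0, 1] inside the simulated
horizon raises an error, except for laws explicitly flagged to saturate
at 1 — needed only by the strongly boosted networking variants of the
high-energy-demand scenario, where the growing fission law reaches 1
around t ≈ 3.5·10⁴ tu and the natural probabilistic reading is "the
process fires every step".

### The five operators

* **Metabolic fission/fusion** — for every ordered pair (q₁, q₂) of
  active states with even sum, weight ρ_FFm(t)·P(q₁)·P(q₂)·h(|q₁−q₂|)
  moves both partners to the common midpoint.  h is the Hill rate
  Δ^FF1/(FF2^FF1 + Δ^FF1).  Odd-sum pairs cannot satisfy the integer
  midpoint constraint and contribute nothing (splitting them across the
  two adjacent states was evaluated and rejected: it breaks the
  combined-networking benchmark).  The operator conserves total
  probability and the first moment exactly.
* **Proteinaceous fission/fusion** — fusion raises the lower partner of
  an active pair to the higher quality with rate ρ_Fup(t)·h(|q₁−q₂|);
  fission sends one member of a like-quality pair (encounter weight
  P(q)²) to the inactive state with rate ρ_Fip(t)·h(Q−q), so low-quality
  mitochondria fission preferentially.  Pair encounters are counted once
  per ordering — either partner can play either role — giving both terms
  a factor 2 relative to an unordered-pair count.  This convention is
  required jointly by the proteinaceous-only and combined-networking
  benchmarks (the unordered count leaves the combined run far too
  fission-heavy, P(0) ≈ 0.74 instead of ≈ 0.44).  The whole term is
  scaled by the balance constant γ (default 1).
* **Mitophagy/biogenesis** — coupled flux ρ_mb(t)·P(0) out of q = 0 and
  into q = Q; mass-conserving by construction.
* **Repair** — a row-stochastic binomial kernel: from state q′ each of
  the Q−q′ missing quality units is independently restored with
  probability ρ_rep(t); the net flux is (KᵀP − P).  Never decreases q̄.
* **Energy consumption** — the mirrored binomial kernel: each of a
  state's q′ units is lost with probability ρ_ec(t); never increases q̄.
  For both kernels the time-dependent probability is embedded in the
  kernel itself rather than factored out as a prefactor (the prefactor
  variant was evaluated and is grossly inconsistent with the benchmark
  scenarios).
* **External damage** — the only stochastic element: once per step, with
  probability ρ_ed(t), one pair (q′ > q) is drawn uniformly and the
  fraction f_rd of P(q′) moves to P(q).  It is applied as a discrete map
  on probabilities after the deterministic Euler update, not as a rate
  term.  The per-step event count is not uniquely determined by the
  model's description; one gated event per step was chosen after
  verifying that the alternatives (intensity-scaled transfer every step,
  two events, per-donor events, mean-field transfer) give statistically
  indistinguishable trajectories at the reference parameters.

### Parameters (reference values)

| parameter | meaning | default |
|---|---|---|
| γ | metabolic vs proteinaceous networking balance | 1 |
| ρ0_FFm, τ_FFm | metabolic networking, decaying | 0.05, 50000 tu |
| ρ0_FFp, τ_FFp | proteinaceous fusion (decay) / fission (growth) | 0.05, 50000 tu |
| FF1, FF2 | Hill coefficients of all networking rates | 2, 3 |
| ρ0_mb, τ_mb | recycling, growing | 0.01, 50000 tu |
| ρ0_rep, τ_rep | repair, decaying | 0.01, 50000 tu |
| ρ0_ec, τ_ec | internal ROS damage, growing | 0.01, 50000 tu |
| ρ0_ed, τ_ed | external ROS damage, growing | 0.01, 50000 tu |
| f_rd | fraction moved per external-damage event | 0.03 |

Networking is five times more frequent than the other processes; all
other starting probabilities are equal (principle of indifference), and
all lifetimes are equal.  These values are relative estimates, not
literature-derived quantities, so the model supports qualitative, not
quantitative, conclusions about real cells.  Scenario presets encode the
documented variants: single processes and the networking/recycling
interplay (30000 steps), aging and non-aging cells, stable repair,
stressed cells (ρ0_ec = 0.05, ρ0_ed = 0.1, f_rd = 0.3), high-energy-demand
cells (ρ0_ec = 0.05) with networking/recycling rescue strategies, and
doubled-parameter robustness variants.

## Integration and numerical choices

Explicit Euler with the left-point rule: all rate laws are evaluated at
each step's start time.  After the summed deterministic update the
external-damage map is applied, then the state is validated: any entry
below −10⁻¹² or a total differing from 1 by more than 10⁻¹² aborts the
run with a diagnostic naming the state and step.  Aborting (rather than
clamping and renormalizing) is deliberate: silent renormalization would
mask conservation violations.

Two floating-point hygiene measures keep the 12-decimal norm criterion
honest over 10⁵ steps: the per-step flux sum's rounding residual (a few
ULPs; anything above 10⁻¹³ still aborts as a genuine conservation bug) is
subtracted uniformly from the update, and the external-damage two-bin
transfer is compensated exactly.  Without these, accumulated rounding —
not model error — crosses the 10⁻¹² guard after roughly 7·10⁴ steps.

Metrics (q̄, σ_q, P(0), N_prob) are recorded at t = 0, every
`record_every` steps, and a closing row for the final state is always
appended, so a metrics table has ⌊n_steps/record_every⌋ + 2 rows.  q̄ is
the plain first moment on the 0..Q scale; σ_q is the mean absolute
deviation (not a standard deviation).  With a fixed seed, trajectories
are bit-identical across runs; only the external-damage process consumes
randomness (one uniform draw per step, one more per event).

Benchmark problem sizes: deterministic scenarios run 30000 steps,
full-system scenarios 100000 steps, and stochastic metrics are averaged
over ten seeds — the conditions under which the reference values were
defined.

## What the simulations do and do not show

The scenarios are self-contained mathematical experiments: there is no
external data, and the presets *are* the study conditions.  Passing the
benchmark checks shows that the implementation reproduces the model's
published behaviour, not that the model quantitatively describes any real
cell type — the parameters are relative estimates, quality is a
one-dimensional summary, mitochondrial mass is only tracked
probabilistically, and couplings between processes (e.g. between
oxidative stress and recycling) are deliberately neglected.

## Known limitations

* All eight deterministic benchmark end-points (networking variants,
  recycling, interplay) are reproduced to within 0.03 absolute, and the
  stochastic end-points of the aging scenario to within 10%.  Three
  full-system details deviate and are kept as deliberately failing
  acceptance tests: the aging q̄ minimum has the right depth but occurs
  late (≈ 8·10⁴ tu rather than ≈ 7·10³ tu) because the trajectory first
  rises under repair and fusion before declining, P(0, t) dips by ≈ 0.03
  early before growing monotonically, the non-aging fixed point sits at
  P(0) = 0.072 rather than 0.095 (q̄ and σ_q agree within 10%), and the
  high-energy-demand q̄ levels off near 1.33 rather than 1.65 (its P(0)
  agrees within 3%).  The explored interpretation space (pair-counting
  conventions, operator splitting, kernel prefactors, odd-pair mixing,
  external-damage scheduling) contains no variant that removes these
  deviations without breaking the benchmarks that pin the operators.
* The integrator is first-order; halving Δt changes deterministic
  end-points by well under the benchmark tolerances, but stiff parameter
  regimes (rates approaching 1 per step) rely on the integrity guard to
  detect overshoot rather than adapting the step.
* More than 15 quality states unbalances the processes (fission's Hill
  rate saturates while the binomial kernels sharpen), so Q is restricted
  to 4–14.
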