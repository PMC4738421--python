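"""The interplay of mitochondrial networking and recycling.

Metabolic ("kiss and run") fission/fusion only mixes metabolites; the
proteinaceous part raises qualities by fusion but feeds the inactive
state by fission.  Recycling alone stalls once no inactive mitochondria
remain.  Together, fission keeps supplying inactive mitochondria for
mitophagy, whose coupled biogenesis re-creates them at top quality -- so
the combination pumps the whole population to the maximal state.
"""

from mitoq import build_scenario, run_simulation

for name in ["ff_metabolic_only", "ff_protein_only", "single_ff", "single_mb", "interplay"]:
    m = run_simulation(build_scenario(name).config).final_metrics
    print(f"{name:18s} qbar={m.qbar:6.3f}  sigma_q={m.sigma_q:6.3f}  P(0)={m.p0:6.3f}")

print(
    "\nNeither networking nor recycling raises quality much on its own, but"
    "\ntheir interplay drives qbar to 10 with no inactive mitochondria left."
)
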