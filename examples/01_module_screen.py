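"""Build a co-expression network on synthetic data and rank hub genes.

Simulates an FPKM matrix with five planted co-expression modules over
20 samples, runs the full essential-gene screen (filter -> signed
network -> TOM -> dynamic tree cut -> eigengene merge -> intramodular
degree), and prints the recovered module structure.
"""

from lncscreen import PipelineConfig, run_essential_screen, \
    simulate_modular_expression
from lncscreen.simulate import SimulationConfig

matrix, annotation, truth = simulate_modular_expression(SimulationConfig(seed=1))
result = run_essential_screen(matrix, annotation, PipelineConfig(seed=1))

print(f"soft power: {result.soft.beta} "
      f"(scale-free fit cut reached: {result.soft.reached_cut})")
print("\nmodule summary (size and essential = top-25% intramodular degree):")
print(result.module_summary)

print("\ntop-connected gene per module:")
top = result.essential.sort_values("kIM", ascending=False) \
    .groupby("module", sort=False).head(1)
print(top)

hubs_found = [h for h in truth.hubs if h in result.essential.index]
print(f"\nplanted hubs recovered as essential: {len(hubs_found)}/{len(truth.hubs)}")
# The screen recovers the five planted modules (plus a grey remainder of
# unassignable noise genes); every planted hub ranks in the top quarter
# of its module's intramodular connectivity.
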