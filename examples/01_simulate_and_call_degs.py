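"""Simulate a 24-array low-P experiment and call DEGs for one contrast.

The generator plants up/down shifts on the low-P groups of chosen design
cells; the SAM-style test should recover them while calling essentially
nothing on unplanted genes.
"""

import lowphos as lp

spec = lp.default_scenario(rng_seed=1, n_genes=1000)
matrix, sheet, truth = lp.simulate_dataset(spec)
print(f"simulated {matrix.shape[0]} genes x {matrix.shape[1]} arrays")

config = lp.PipelineConfig()
contrast = lp.standard_contrasts(sheet)["treatment_tolerant_root"]
result = lp.test_contrast(matrix, contrast, config)

called = set(result.index[result["is_deg"]])
planted = truth.treatment_deg_ids("tolerant", "root")
up = int((result["direction"] == "up").sum())
down = int((result["direction"] == "down").sum())
print(f"low P vs normal P in tolerant roots: {up} up, {down} down DEGs")
print(f"planted treatment DEGs recovered: {len(called & planted)}/{len(planted)}")

# every call should correspond to a real planted shift (treatment DEGs plus
# pattern genes whose low-P shift implies a treatment effect)
true_eff = truth.contrast_effect(
    ("tolerant", "root", "lowP"), ("tolerant", "root", "normalP")
)
false_calls = [g for g in called if abs(true_eff.loc[g]) < 1]
print(f"calls without a planted effect: {len(false_calls)}")
print("(a DEG = |log2 ratio| >= 1, permutation FDR < 0.05, 3 replicates)")
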