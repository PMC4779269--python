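"""Hypergeometric term enrichment of a DEG list against the array background.

A toy annotation is simulated with one term over-representing the DEG
subset 8-fold; that term should surface with the smallest p-value.
"""

import lowphos as lp

universe = [f"g{i:03d}" for i in range(500)]
degs = set(universe[:60])

annotation = lp.simulate_annotation(
    universe,
    n_terms=10,
    seed=7,
    enriched_terms={"TERM0001": 8.0},
    target_genes=degs,
)

config = lp.PipelineConfig()
table = lp.enrich_sets(degs, annotation, set(universe), config)
cols = ["term_id", "N", "K", "n", "k", "p_value", "enriched"]
print(table[cols].head(5).to_string(index=False))
top = table.iloc[0]
print(
    f"\ntop term {top['term_id']}: {top['k']} of its {top['K']} genes in the "
    f"{top['n']}-gene query (P = {top['p_value']:.2e})"
)
print("(p = upper-tail hypergeometric probability of the overlap against the")
print(" measured background; 'enriched' flags raw p < 0.05)")
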