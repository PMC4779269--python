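"""Cross-classify inter-accession DEGs by their normal-P behaviour.

Low-P DEGs of the tolerant/sensitive comparison fall into four categories:
concordant (same difference under normal P), opposite, rescued (>4-fold
under low P despite no normal-P difference) and dropped. Marked DEGs =
opposite + rescued: the accession differences specific to low P.
"""

import pandas as pd

import lowphos as lp

config = lp.PipelineConfig()
fixtures = lp.simulate_table2_fixture()  # deterministic printed-table fixture

frames = [
    lp.classify_patterns(low, norm, config, comparison=cmp)
    for cmp, (low, norm) in fixtures.items()
]
patterns = pd.concat(frames, ignore_index=True)
print(lp.category_counts(patterns).to_string(index=False))

material = lp.marked_degs(patterns[patterns["comparison"].str.startswith("material")])
tissue = lp.marked_degs(patterns[patterns["comparison"].str.startswith("tissue")])
print(
    f"\nmarked DEGs between accessions: {material.raw_total} raw, "
    f"{material.nonredundant_count} non-redundant"
)
print(f"marked DEGs between tissues: {tissue.nonredundant_count}")
print("(raw > non-redundant because one rescued gene appears in both the")
print(" root and leaf accession comparisons)")
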