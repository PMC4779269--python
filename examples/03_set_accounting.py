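"""Non-redundant union and multi-way overlap of DEG sets.

The treatment-contrast DEG sets overlap across cells (a transcript can
respond in two tissues); the accounting reports raw totals, distinct ids
and who is shared. Intersecting the treatment DEGs with both marked-DEG
sets gives the "common DEGs" — active genes under low-P stress.
"""

import lowphos as lp

sets = lp.simulate_table1_fixture()
acc = lp.nonredundant_union(sets)
print("treatment DEG sets:", {k: len(v) for k, v in sets.items()})
print(f"raw total {acc.raw_total}, non-redundant {acc.distinct_count}")
for gene, names in acc.duplicates.items():
    print(f"  shared: {gene} in {', '.join(names)}")

ov = lp.simulate_overlap_fixture()
tm = lp.overlap_genes(ov["treatment"], ov["marked_material"])
tt = lp.overlap_genes(ov["treatment"], ov["marked_tissue"])
common = lp.overlap_genes(*ov.values())
print(f"\ntreatment ∩ marked-material: {len(tm)} genes")
print(f"treatment ∩ marked-tissue:   {len(tt)} genes")
print(f"common to all three:         {len(common)} genes")
print("(the common genes respond to low P and differ between accessions")
print(" and between tissues — the strongest low-P candidates)")
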