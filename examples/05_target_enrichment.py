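"""Map miRNAs to validated targets and test pathway over-representation.

Uses the packaged demo target map and pathway collection (illustrative
stand-ins for curated databases). The hypergeometric upper tail asks
whether a pathway contains more of the pooled target genes than a random
draw of the same size from the collection's gene universe; Bonferroni
corrects across the pathways tested.
"""

from mirnet import read_gmt, read_target_map, targets_of, enrich
from mirnet.data import demo_gmt_path, demo_target_map_path

tmap = read_target_map(demo_target_map_path())
sets = read_gmt(demo_gmt_path())

mirnas = {"hsa-miR-563", "hsa-miR-199b-5p", "hsa-miR-323-3p"}
genes = targets_of(mirnas, tmap, mode="union")
print(f"{len(mirnas)} miRNAs -> {len(genes)} pooled target genes "
      f"(universe {sets.universe_size})")

per = targets_of(mirnas, tmap, mode="per_mirna")
for m, gs in sorted(per.items()):
    print(f"  {m}: {len(gs)} targets")

results = enrich(genes, sets)
print("top enriched pathways (hypergeometric, Bonferroni over "
      f"{len(sets)} sets):")
for r in results[:4]:
    flag = "*" if r.significant else " "
    print(f" {flag}{r.set_name}: {r.overlap}/{r.set_size} genes, "
          f"p={r.p_value:.2e}, Bonferroni={r.p_bonferroni:.2e}")
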