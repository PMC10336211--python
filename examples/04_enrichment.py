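"""Gene-set over-representation of a discovered-protein list.

The universe is the coding genes of all proteins tested in the screen (the
assay panel defines the sampling frame); a term containing many discovered
genes gets a small hypergeometric tail p, adjusted across terms by
Benjamini–Hochberg.  A user-supplied druggability table annotates hits."""

import pandas as pd

from pqtlmr import druggability_join, hypergeom_enrich

universe = [f"GENE{i}" for i in range(60)]
hits = [f"GENE{i}" for i in range(8)]          # discovered coding genes
terms = {
    "matrix_organization": set(universe[0:10]),     # 8/10 overlap with hits
    "signalling": set(universe[5:25]),              # mild overlap
    "housekeeping": set(universe[30:55]),           # no overlap
    "tiny_term": set(universe[0:2]),                # below min_term, skipped
}

table = hypergeom_enrich(hits, universe, terms, min_term=3, max_term=500)
print(table.to_string(index=False))
print("\n'matrix_organization' holds 8 of the 8 hits against a universe of 60,")
print("so its tail p is tiny and survives BH adjustment; terms smaller than")
print("min_term are never tested.")

tiers = pd.DataFrame({"gene": ["GENE0", "GENE3"], "tier": ["1", "2"]})
print("\ndruggability annotation of the hits:")
print(druggability_join(hits, tiers).to_string(index=False))
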