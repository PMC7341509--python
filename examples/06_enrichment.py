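"""Hypergeometric gene-set over-representation with BH FDR correction."""

import numpy as np

import divscan as d

rng = np.random.default_rng(6)
genes = [f"g{i}" for i in range(500)]
terms = {f"pathway_{j}": set(rng.choice(genes, size=25, replace=False)) for j in range(20)}
term_map = d.TermMap(terms, set(genes))

# a query deliberately loaded with most of pathway_1's genes
query = set(list(terms["pathway_1"])[:18]) | set(rng.choice(genes, size=30, replace=False))
table = d.hypergeometric_enrichment(query, term_map)

print(table.head(5).to_string(index=False, float_format=lambda v: f"{v:.3g}"))
n_sig = int(table["significant_fdr"].sum())
print(f"\n{n_sig} term(s) significant after FDR correction (adjusted p < 0.05)")
# pathway_1 tops the table with a tiny p-value because ~18 of its 25
# genes appear in the query; unrelated pathways hover near uniform p.
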