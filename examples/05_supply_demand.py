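"""tRNA supply vs codon demand: correlation and the supply/demand ratio.

Supply is the relative level of each isoacceptor family (percent of the
tRNA pool); demand is the expression-weighted usage of its Watson-Crick
cognate codon (the reverse complement of the anticodon).  Codons reached
only by wobble decoding are excluded.  The ratio supply%/demand% flags
families that are scarce (ratio < 1) or buffered (ratio > 1) relative to
how often their codon must be read.
"""

import numpy as np
import pandas as pd

import trnapool as tp
from trnapool.codon import codon_count_matrix

study = tp.simulate_study(tp.SimConfig(seed=9, n_transcripts=1000,
                                       n_cell_types=4))
cm = study.chip
iso = tp.aggregate(tp.relative_expression(cm), "isoacceptor", cm.records())
levels = iso.cell_type_levels()
mat, _ = codon_count_matrix(study.cds)

cts = list(levels.columns)
usages = {}
for ct in cts:
    cols = [c for c in study.tpm.columns if c.rsplit("_", 1)[0] == ct]
    usages[ct] = tp.weighted_codon_usage(mat, study.tpm[cols].mean(axis=1),
                                         context=ct)

rho, pairs = tp.codon_anticodon_correlation(levels[cts[0]], usages[cts[0]])
n_inc = int(pairs["included"].sum())
print(f"{cts[0]}: Spearman rho(family level, cognate usage) = {rho:.3f} "
      f"over {n_inc} Watson-Crick pairs")

# matched (same cell type) vs mismatched (cross cell type) correlations
rho_mat = pd.DataFrame(index=cts, columns=cts, dtype=float)
for a in cts:
    for b in cts:
        rho_mat.loc[a, b], _ = tp.codon_anticodon_correlation(levels[a],
                                                              usages[b])
u, p = tp.matched_mismatched_test(rho_mat)
print(f"matched vs mismatched Mann-Whitney p = {p:.3f} "
      "(near 1 = a cell type's tRNA pool is no better tuned to its own "
      "translatome than to others')")

table = tp.supply_demand_ratio(levels[cts[0]], usages[cts[0]])
table = table[table["ratio"].notna() & (table["trna_pct"] > 0)]
print("\nmost buffered families (supply% / demand%):")
print(table.nlargest(3, "ratio")[["cognate_codon", "trna_pct", "codon_pct",
                                  "ratio"]].round(3).to_string())
print("\nscarcest families:")
print(table.nsmallest(3, "ratio")[["cognate_codon", "trna_pct", "codon_pct",
                                   "ratio"]].round(3).to_string())
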