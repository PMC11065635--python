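"""Quantify the tRNA pool: occupancy, relative levels, family diversity.

A tRNA gene counts as occupied in a cell type when every replicate has
more than 2 reads over its locus.  Relative levels are fractions of all
tRNA-mapped reads; summing them within an anticodon family gives
isoacceptor levels, and the fraction of genes contributing >5% of their
family measures pool diversity.
"""

import trnapool as tp

study = tp.simulate_study(tp.SimConfig(seed=42, n_transcripts=500))
cm = study.chip

occ, any_ct = tp.classify_expressed(cm, min_reads=2)
print(f"occupied in >=1 cell type: {int(any_ct.sum())}/{len(any_ct)} genes")

expr = tp.relative_expression(cm)          # tRX dropped, fractions sum to 1
iso = tp.aggregate(expr, "isoacceptor", cm.records())
levels = iso.cell_type_levels()
ct = levels.columns[0]
top = levels[ct].nlargest(3)
print(f"\ntop isoacceptor families in {ct} (fraction of tRNA pool):")
for fam, v in top.items():
    print(f"  {fam:<10} {v:.3f}")

# identical-mature collapse: Ile-TAT-2-1/-2/-3 style groups become one unit
collapsed = tp.collapse_identical(cm)
print(f"\n{len(cm.genes)} genes -> {collapsed.counts.shape[0]} distinguishable units")

comp = tp.family_composition(
    tp.FamilyExpressionTable("gene", levels_g := expr.cell_type_levels(),
                             cm.sample_sheet.drop_duplicates(subset="cell_type")
                             .set_index("cell_type", drop=False)
                             .loc[list(levels_g.columns)]),
    cm.records())
overall, _ = tp.diversity_fraction(comp, threshold=0.05)
print("\nfraction of genes contributing >5% of their family, per cell type:")
print(overall.round(3).to_string())
# Higher values mean the anticodon pools are spread over more genes
# (a more heterogeneous tRNA repertoire).
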