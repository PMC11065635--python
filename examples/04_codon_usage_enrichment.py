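"""Expression-weighted codon usage and permutation enrichment.

Codon demand of a cell type = codon counts of every CDS weighted by its
TPM, normalised over the 61 sense codons to percentages.  For a
cell-type-specific gene set (>=50-fold TPM difference), each codon's
usage is compared with 10,000 random same-size sets: codons few random
sets beat are over-represented (empirical p_high <= 0.05).
"""

import trnapool as tp
from trnapool.codon import codon_count_matrix

study = tp.simulate_study(tp.SimConfig(
    seed=3, n_transcripts=2000, planted_codon="GAA",
    planted_codon_shift=0.10, planted_set_size=80, n_cell_types=4))
mat, rejected = codon_count_matrix(study.cds)
print(f"codon-counted {len(mat)} transcripts ({len(rejected)} rejected)")

ct_a, ct_b = list(study.truth.specific_transcripts)
tpm = study.tpm
mean = {ct: tpm[[c for c in tpm.columns if c.rsplit('_', 1)[0] == ct]].mean(axis=1)
        for ct in (ct_a, ct_b)}

usage = tp.weighted_codon_usage(mat, mean[ct_a], context=ct_a)
print(f"\n{ct_a} usage sums to {usage.usage.sum():.6f}% over 61 codons")

set_a, set_b = tp.specific_gene_sets(mean[ct_a], mean[ct_b], fold=50)
print(f"{ct_a}-specific transcripts (>=50-fold): {len(set_a)}")

res = tp.empirical_codon_enrichment(mat, mean[ct_a], set_a,
                                    n_perm=10_000, seed=1)
over = res[res.flag_over].sort_values("p_high")
print(f"\nover-represented codons in the {ct_a}-specific set:")
print(over[["observed_pct", "null_mean_pct", "p_high"]].head(5).round(4)
      .to_string())
print(f"\nplanted codon GAA over-represented: {bool(res.loc['GAA', 'flag_over'])}")
# p_high is the fraction of the 10,000 random sets whose usage of the
# codon is strictly higher than the observed set's.
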