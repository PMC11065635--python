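"""Generate a synthetic cell-type tRNA study and write it to disk.

The generator emulates an 11-cell-type nervous-system design: a gtRNAdb-style
tRNA catalogue, Pol III ChIP-seq count matrices (2 replicates/cell type,
negative-binomial noise), and per-cell-type translatomes (CDS + TPM,
3 replicates).  Everything planted is recorded in a ground-truth JSON.
"""

from pathlib import Path

import trnapool as tp
from trnapool import io

out = Path("scratch/example_study")
cfg = tp.SimConfig(seed=42, n_transcripts=2000, planted_codon="GAA")
study = tp.simulate_study(cfg)

out.mkdir(parents=True, exist_ok=True)
io.write_annotation(study.annotation, out / "trna_annotation.bed",
                    out / "trna_annotation.tsv")
io.write_matrix(study.chip.counts, out / "chip_counts.tsv", "gene")
io.write_sample_sheet(study.chip.sample_sheet, out / "sample_sheet.tsv")
io.write_fasta(study.cds, out / "cds.fasta")
io.write_matrix(study.tpm, out / "tpm.tsv", "transcript")
io.atomic_write_text(out / "ground_truth.json", study.truth.to_json())

n_trx = sum(r.is_trx for r in study.annotation)
print(f"tRNA genes:            {len(study.annotation)} ({n_trx} tRX)")
print(f"ChIP samples:          {study.chip.counts.shape[1]}")
print(f"transcripts:           {len(study.cds)}")
print(f"planted 2-fold genes:  {len(study.truth.differential_trna_genes)}")
print(f"planted codon shift:   {study.truth.biased_codons}")
print(f"written to:            {out}/")
# The counts matrix is the input every downstream stage consumes; the
# ground truth lets you score how well each stage recovers what was planted.
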