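# Methods

`trnapool` quantifies cell-type-resolved tRNA expression from RNA
polymerase III ChIP-seq read counts, estimates codon demand from
translatomes, and relates the two.  This note records the models, the
parameters that matter, the numerical conventions, and the limits of what
the synthetic-data tests demonstrate.

## tRNA pool quantification

Pol III ChIP-seq read density over a tRNA locus proxies its transcription.
The unit of expression throughout is the **relative level**: a gene's
fraction of all tRNA-mapped reads in a sample,

    value(g, s) = count(g, s) / Σ_g' count(g', s).

Genes annotated tRX (ambiguous isotype/anticodon) are removed *before*
normalisation and logged; low-confidence genes can optionally be removed
the same way.  Cell-type levels are the **mean of replicate fractions**,
not pooled raw counts, so each replicate carries equal weight regardless
of sequencing depth; the pooled-count alternative would weight deeper
libraries more and is deliberately not the default (the choice is isolated
in `FamilyExpressionTable.cell_type_levels` and easy to swap).

A gene is **occupied** (expressed) in a cell type when its count is
strictly greater than `min_reads = 2` in *every* replicate of that cell
type — the two-replicate "both > 2 reads" rule generalised to any
replicate number.  A single-replicate cell type degenerates to that one
sample, with a warning.

Aggregation sums gene fractions into isoacceptor families (same
anticodon), isotypes (same amino acid) or transcript groups
(identical mature sequence, e.g. Ile-TAT-2-{1,2,3}); it is linear, so
per-sample totals are conserved and aggregation commutes with
normalisation.  Family composition is each gene's share of its family's
level; zero-total families are reported as undefined (NaN), never as
zeros.  The **diversity metric** is the fraction of genes contributing
strictly more than 5% of their isoacceptor family; the strict inequality
means a 0.90/0.05/0.05 family has exactly one significant contributor.

## Differential expression

Per unit (gene, group, family or isotype), replicate-level fractions of
the two groups are compared with a variance-gated two-sample t-test: a
two-sided F-test on the variance ratio at `gate_alpha = 0.05` selects
Welch's t-test (Satterthwaite df) when it rejects and Student's pooled
t-test otherwise.  `gate_alpha` is a convention (the procedure is not
sensitive to it in the simulations here) and is recorded in run metadata.
Degenerate inputs — zero variance in both groups — return p = 1 for equal
means and p = 0 (flagged) otherwise.  P-values within one resolution are
Benjamini-Hochberg adjusted (via statsmodels); a unit is significant when
q ≤ 0.05 **and** |log2FC| ≥ 0.5.  Fold changes are computed on relative
fractions with a pseudocount of half the smallest nonzero fraction at that
resolution, which keeps log-ratios finite without dominating observed
values.  When a group spans several cell types, all replicate-level
fractions of its member cell types enter the test (n = Σ replicates);
using cell-type means as samples instead is possible by aggregating before
calling, but is not the default because it discards within-cell-type
replication.

The high-variance screen computes, per unit, the variance of cell-type
means across cell types (population variance) and the replicate variance
within each cell type; units where any within-cell-type variance strictly
exceeds the population variance are dropped, survivors are ranked by
population variance descending with name tie-breaks for determinism.

## Codon demand and supply/demand

Codon counts are taken frame-0 from each CDS; stop codons never count, a
single terminal stop is tolerated, and under the default policy a CDS with
a non-multiple-of-3 length, an internal stop or a non-ACGT base is
rejected with a reason (a `tolerate` policy counts what it can).  Where
several CDS map to one gene, the longest is kept, ties broken by
transcript id.  Expression-weighted usage of codon c in a cell type is

    usage(c) = 100 · Σ_t n_t(c)·tpm_t / Σ_c' Σ_t n_t(c')·tpm_t ,

a percentage over the 61 sense codons (sums to 100, invariant to TPM
rescaling; transcripts with tpm = 0 contribute nothing).

**Cognate** means exact Watson-Crick pairing only: the cognate codon of an
anticodon is its reverse complement.  Wobble and near-cognate decoding are
never inferred; sense codons whose exact-anticodon family is absent or
unexpressed are excluded from correlation analyses with the recorded
reason "wobble-only decoding", and families whose reverse complement is a
stop codon have no cognate.  The codon-anticodon correlation is Spearman's
ρ (average ranks on ties) between family levels and cognate-codon usage
over the included pairs; matched (same cell type) versus mismatched
(cross-cell-type) correlations are compared with a two-sided Mann-Whitney
U.  The supply/demand ratio is family level (%) divided by cognate codon
usage (%); zero usage is an error, not an infinite ratio.

Cell-type-specific gene sets use the fold rule
(tpm_A + pseudo)/(tpm_B + pseudo) ≥ 50 with pseudo = 0.01 TPM.

## Empirical permutation tests

Both permutation procedures share one sampling engine: uniform
transcript sets drawn without replacement within a set, independent
across permutations, reproducible from a seed, and generated in
vectorised blocks (each set is the index set of the k smallest of n iid
uniform keys; indices are sorted so an identical subset always sums in
the same floating-point order and ties with the observed set are exact).

*Codon enrichment*: one pass of `n_perm = 10,000` random same-size sets
serves all 61 codons.  Per codon, `p_high` is the fraction of random sets
with strictly higher usage than the observed set and `p_low` the fraction
strictly lower; ties are counted separately, so the three fractions sum to
1 exactly.  A codon is over-represented when p_high ≤ 0.05 and
under-represented when p_low ≤ 0.05.

*Correlation null*: each permutation draws two independent (not disjoint)
random sets of the observed sizes, computes each set's weighted usage in
its own cell type, and correlates the two 61-vectors (Pearson); `p_low`
answers "is the observed correlation lower than chance predicts".

The default p-value is the plain fraction, which can be exactly 0; the
smoothed estimator (r+1)/(n_perm+1) is available via `smoothed=True`,
never vanishes, and is super-uniform under the null — recommended when
p-values feed downstream multiplicity corrections.

## Descriptive machinery

Row z-scores use the sample sd (ddof = 1); constant rows become zero and
are flagged.  PCA is SVD on centered (optionally unit-variance) data with
a fixed sign convention (largest-magnitude loading positive).  Clustering
uses Euclidean distances with average linkage and a deterministic
smallest-subtree-first leaf order (equal sizes break on the smallest leaf
label); this reproduces cluster *membership*, not the exact leaf order of
any particular published dendrogram-sorting heuristic.  The frequency-
distribution fit histograms the values at a given bin width and
least-squares fits A·exp(−(x−μ)²/2σ²) to bin-center counts, initialised
at the sample mean/sd and the max bin count.

## Synthetic-data generator

The generator emulates the design of a cell-type tRNA atlas of the
nervous system and is the test bed for every stage.  Defaults (all in
`SimConfig`):

| parameter | default | rationale |
|---|---|---|
| n_families | 49 | distinct anticodon families in a mammalian catalogue |
| genes_per_family | 3–15 | ~440 genes, the scale of a curated mm10 set |
| n_identical_groups | 10 | identical-mature groups (Ile-TAT-2-style) |
| trx_fraction / low_confidence_fraction | 0.04 / 0.14 | catalogue composition |
| inactive_fraction | 0.35 | Pol III-silent genes; low-confidence first |
| n_cell_types | 11 | 4 group-1 neurons, 3 group-2 neurons, 4 non-neuronal |
| n_replicates_per_cell_type / n_tpm_replicates | 2 / 3 | ChIP vs translatome replication |
| library_depth | 10⁶ | tRNA-mapped reads per sample |
| nb_dispersion (φ) | 0.05 | NB variance μ + φμ²; φ = 0 is Poisson |
| expression_logsd | 1.5 | spread of gene propensities (pool dominated by a few families) |
| n_transcripts | 5,000 | desk-scale translatome; raise to ~27,000 for full scale |
| cds_length_codons | 100–1,000 | mammalian CDS range |
| tpm_logsd / tpm_celltype_sd | 2.0 / 0.5 | within/between-cell-type expression spread |
| specificity_fold | 50 | planted cell-type-specific separation |
| planted_codon_shift | 0.10 | additive relative-frequency shift in the planted set |

Counts are gamma-Poisson (mean/dispersion NB).  Planted differential
genes split the effect symmetrically (×2^(lfc/2) in one group,
×2^(−lfc/2) in the other) and are always drawn from the active pool.
Depth scaling happens *before* planting so expected counts realise the
planted fold exactly; the analysed fractions still feel the (small)
compositional shift, as they would in a real experiment.  CDS are
ATG + sense-codon body + one stop; the planted set's codon frequency is
raised additively and renormalised.  TPMs share one per-transcript level
across cell types (modulated by `tpm_celltype_sd`), are renormalised to
10⁶ per sample, and planted specific transcripts are pinned to a
deterministic 100-fold pre-normalisation separation (50-fold target with
√2 margin); realised post-normalisation ratios are stored in the ground
truth.  All randomness derives from one root seed with per-component
streams, so outputs are byte-identical for identical configs and adding a
generator never perturbs another.

What the generator does **not** model: alignment and fragment-level
coverage, multimapping between near-identical tRNA copies, tRNA body
sequences/modifications, codon order and pair effects within a CDS, GC or
length biases in expression, and correlated biological replicate
structure beyond NB/log-normal noise.  Tests passing on this generator
therefore demonstrate the statistics are implemented and calibrated as
specified — not that real ChIP-seq quantification upstream of the counts
is unbiased.

## Problem sizes used in the automated checks

Calibration uses 10,000 null Gaussian features (n = 5/group) and 200
uniformity repeats at 1,000 permutations; recovery uses ~500 genes with
50 planted 2-fold effects at 5 replicates/group and φ = 0.02 (chosen as a
"moderate" biological dispersion — ~14% extra-Poisson CV on well-covered
genes — at which the stated design has adequate power), and 10–20
regenerated translatomes (universe 5,000, set 100, shift +0.10, 10,000
permutations) for codon-enrichment recovery.  The exhaustive-null check
compares Monte-Carlo p-values against all 56 subsets of an 8-transcript
universe.  These sizes are the package's own choices for fast, convincing
checks; every routine accepts larger inputs unchanged.

## Known limitations

- The F-test gate is known to perturb the t-test's size slightly in
  theory; on Gaussian nulls at n = 5/group the realised type-I error stays
  within [0.04, 0.06], which is what the calibration check asserts.
- Plain-fraction empirical p-values can be 0; use `smoothed=True` for
  downstream multiplicity work.
- With 2 replicates per cell type (the atlas design) the t-tests are
  fragile; the generator's replicate count is configurable precisely so
  analyses can be rehearsed at higher n.
- `aggregate`/`collapse_identical` trust the name-encoded transcript
  groups; no sequence-level identity check is performed.
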