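"""Synthetic study generator: tRNA catalogues, Pol III ChIP count matrices
and translatomes (CDS + TPM) with known ground truth.

The generator emulates the structure of a cell-type-resolved tRNA atlas of
the nervous system: a gtRNAdb-style gene catalogue with isoacceptor
families, identical-mature-sequence groups, tRX and low-confidence genes;
per-cell-type ChIP-seq count matrices with negative-binomial replicate
noise and planted group differences; and per-cell-type translatomes with
log-normal expression, planted cell-type-specific transcripts (>=50-fold)
and planted codon-usage shifts.  Every planted effect is recorded in a
:class:`GroundTruth` so downstream statistics can be scored for recovery.

Randomness: a single root seed; each component derives its own stream from
(seed, component-name), so adding one generator never perturbs another and
identical configs give byte-identical outputs.
"""

from __future__ import annotations

import json
import logging
import zlib
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .genetic_code import SENSE_CODONS, SENSE_INDEX, STOP_CODONS, codon_to_anticodon, CODON_TO_AA3
from .quant import CountMatrix, TRNAGeneRecord

log = logging.getLogger(__name__)


class ConfigError(ValueError):
    """Invalid simulation configuration."""


@dataclass
class SimConfig:
    """Knobs of the synthetic study.

    Defaults mirror the design of the emulated atlas: 49 isoacceptor
    families of 3-15 genes (~440 genes), 11 cell types (4 group-1 neurons,
    3 group-2 neurons, 4 non-neuronal), 2 ChIP replicates and 3 translatome
    replicates per cell type, ~14% low-confidence genes, 10,000-permutation
    scale universes.  ``nb_dispersion`` is the phi of a mean/dispersion
    negative binomial (variance = mu + phi mu^2); phi = 0 degenerates to
    Poisson.
    """

    seed: int = 0
    # --- tRNA catalogue ---
    n_families: int = 49
    genes_per_family: tuple[int, int] = (3, 15)
    n_identical_groups: int = 10
    trx_fraction: float = 0.04
    low_confidence_fraction: float = 0.14
    # --- cell types & ChIP counts ---
    n_cell_types: int = 11
    n_replicates_per_cell_type: int = 2
    library_depth: float = 1_000_000.0
    nb_dispersion: float = 0.05
    expression_logsd: float = 1.5      # spread of per-gene base propensities
    inactive_fraction: float = 0.35    # Pol III-silent genes (low-conf first)
    cell_type_jitter_sd: float = 0.0   # extra per-(gene, cell type) log-noise
    planted_trna_log2fc: float = 1.0
    n_planted_trna: int = 20
    # --- translatome ---
    n_transcripts: int = 5_000
    cds_length_codons: tuple[int, int] = (100, 1_000)
    tpm_logsd: float = 2.0
    tpm_celltype_sd: float = 0.5       # log-scale between-cell-type spread
    n_tpm_replicates: int = 3
    specificity_fold: float = 50.0
    planted_codon: str | None = None
    planted_codon_shift: float = 0.10
    planted_set_size: int = 100

    def validate(self) -> None:
        counts = dict(
            n_families=self.n_families,
            n_identical_groups=self.n_identical_groups,
            n_cell_types=self.n_cell_types,
            n_replicates_per_cell_type=self.n_replicates_per_cell_type,
            n_transcripts=self.n_transcripts,
            n_tpm_replicates=self.n_tpm_replicates,
            planted_set_size=self.planted_set_size,
        )
        for name, v in counts.items():
            if v < 1:
                raise ConfigError(f"{name} must be >= 1, got {v}")
        if self.nb_dispersion < 0:
            raise ConfigError("nb_dispersion must be >= 0")
        lo, hi = self.genes_per_family
        if not (1 <= lo <= hi):
            raise ConfigError("genes_per_family must be a 1 <= lo <= hi range")
        lo, hi = self.cds_length_codons
        if lo < 3:
            raise ConfigError("cds_length_codons lower bound must be >= 3")
        if hi < lo:
            raise ConfigError("cds_length_codons must be a lo <= hi range")
        if self.planted_codon is not None:
            if self.planted_codon not in SENSE_INDEX:
                raise ConfigError(
                    f"planted_codon {self.planted_codon!r} is not a sense codon")
            if not 0 < self.planted_codon_shift < 1:
                raise ConfigError("planted_codon_shift must be in (0, 1)")
        if self.n_planted_trna < 0:
            raise ConfigError("n_planted_trna must be >= 0")
        if self.library_depth <= 0:
            raise ConfigError("library_depth must be positive")


@dataclass
class GroundTruth:
    """Everything that was planted, for recovery scoring."""

    differential_trna_genes: dict[str, float] = field(default_factory=dict)
    specific_transcripts: dict[str, list[str]] = field(default_factory=dict)
    biased_codons: dict[str, float] = field(default_factory=dict)
    realized_specificity: dict[str, dict[str, float]] = field(default_factory=dict)
    underpowered_trna_genes: list[str] = field(default_factory=list)
    contrast_cell_types: tuple[list[str], list[str]] | None = None

    def to_json(self) -> str:
        d = asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)


def _stream(seed: int, name: str) -> np.random.Generator:
    """Component-specific RNG derived from the root seed."""
    return np.random.default_rng([int(seed), zlib.crc32(name.encode())])


def cell_type_design(config: SimConfig) -> pd.DataFrame:
    """Cell-type names with group and class labels.

    Large designs split roughly 4:3:4 into group-1 neurons (N1_*),
    group-2 neurons (N2_*) and non-neuronal cells (NN_*); designs of
    fewer than 5 cell types alternate the two neuronal groups so a
    two-group contrast always exists.
    """
    n = config.n_cell_types
    n_nn = round(n * 4 / 11) if n >= 5 else 0
    rest = n - n_nn
    n_g1 = (rest + 1) // 2
    n_g2 = rest - n_g1
    rows = []
    for i in range(n_g1):
        rows.append((f"N1_{i + 1}", "1", "neuronal"))
    for i in range(n_g2):
        rows.append((f"N2_{i + 1}", "2", "neuronal"))
    for i in range(n_nn):
        rows.append((f"NN_{i + 1}", "NN", "non_neuronal"))
    return pd.DataFrame(rows, columns=["cell_type", "group", "class"])


def generate_trna_annotation(config: SimConfig) -> list[TRNAGeneRecord]:
    """gtRNAdb-style synthetic tRNA catalogue.

    Families take real anticodons (reverse complements of sense codons);
    each family gets 3-15 genes by default, the first
    ``n_identical_groups`` families carry one transcript group with
    multiple identical-mature copies, and configurable fractions of tRX
    and low-confidence genes are appended/flagged.
    """
    config.validate()
    rng = _stream(config.seed, "annotation")
    if config.n_families > len(SENSE_CODONS):
        raise ConfigError(
            f"n_families > {len(SENSE_CODONS)} distinct anticodons available")
    codons = list(SENSE_CODONS)
    rng.shuffle(codons)
    picked = sorted(codons[: config.n_families])
    lo, hi = config.genes_per_family
    records: list[TRNAGeneRecord] = []
    pos = 0
    for fi, codon in enumerate(picked):
        isotype = CODON_TO_AA3[codon]
        anticodon = codon_to_anticodon(codon)
        n_genes = int(rng.integers(lo, hi + 1))
        make_identical = fi < config.n_identical_groups and n_genes >= 2
        group = 1
        g = 0
        while g < n_genes:
            if make_identical and group == 1:
                # one identical-mature group of 2-3 copies, placed first so
                # it always gets >= 2 members
                n_copies = int(min(n_genes - g, rng.integers(2, 4)))
            else:
                n_copies = 1
            for copy in range(1, n_copies + 1):
                name = f"tRNA-{isotype}-{anticodon}-{group}-{copy}"
                start = 1000 * (pos + 1)
                records.append(TRNAGeneRecord(
                    name=name, isotype=isotype, anticodon=anticodon,
                    transcript_group=group, copy=copy,
                    is_trx=False, is_high_confidence=True,
                    chrom="chr1", start=start, end=start + 72,
                    strand="+" if rng.random() < 0.5 else "-",
                ))
                pos += 1
                g += 1
            group += 1
    # low-confidence flags on a fraction of genes
    n_low = int(round(config.low_confidence_fraction * len(records)))
    low_idx = set(rng.choice(len(records), size=n_low, replace=False).tolist())
    records = [
        rec if i not in low_idx else TRNAGeneRecord(
            **{**asdict(rec), "is_high_confidence": False})
        for i, rec in enumerate(records)
    ]
    # tRX genes with ambiguous identity
    n_trx = int(round(config.trx_fraction * len(records)))
    for t in range(n_trx):
        start = 1000 * (pos + 1)
        records.append(TRNAGeneRecord(
            name=f"tRX-NNN-{t + 1}-1", isotype="tRX", anticodon="NNN",
            transcript_group=t + 1, copy=1, is_trx=True,
            is_high_confidence=False,
            chrom="chr1", start=start, end=start + 72, strand="+",
        ))
        pos += 1
    return records


#: propensity multiplier for Pol III-silent genes; at the default depth this
#: leaves well under one expected read per replicate
_INACTIVE_SCALE = 1e-4


def inactive_gene_set(annotation: list[TRNAGeneRecord], config: SimConfig) -> set[str]:
    """Deterministic choice of transcriptionally silent tRNA genes.

    Low-confidence genes are silenced first (in a real catalogue nearly
    all of them are Pol III-free), then high-confidence genes fill the
    remainder of ``inactive_fraction``.
    """
    rng = _stream(config.seed, "activity")
    low = [r.name for r in annotation if not r.is_trx and not r.is_high_confidence]
    high = [r.name for r in annotation if not r.is_trx and r.is_high_confidence]
    n_non_trx = len(low) + len(high)
    n_inactive = int(round(config.inactive_fraction * n_non_trx))
    rng.shuffle(low)
    rng.shuffle(high)
    return set((low + high)[:n_inactive])


def make_ground_truth(
    annotation: list[TRNAGeneRecord], config: SimConfig
) -> GroundTruth:
    """Choose what gets planted (before any data are drawn).

    Planted differential tRNA genes alternate the sign of
    ``planted_trna_log2fc``; the contrast is group-1 vs group-2 neuron
    cell types.  Two designated cell types (the first of each class, or
    first/last) receive ``planted_set_size`` specific transcripts each;
    the codon bias, if configured, is planted in the first cell type's
    specific set.
    """
    config.validate()
    rng = _stream(config.seed, "ground_truth")
    truth = GroundTruth()
    design = cell_type_design(config)
    g1 = design.loc[design["group"] == "1", "cell_type"].tolist()
    g2 = design.loc[design["group"] == "2", "cell_type"].tolist()
    if not g1 or not g2:
        cts = design["cell_type"].tolist()
        g1, g2 = [cts[0]], [cts[-1]]
    truth.contrast_cell_types = (g1, g2)

    silent = inactive_gene_set(annotation, config)
    eligible = [r.name for r in annotation
                if not r.is_trx and r.name not in silent]
    n_plant = min(config.n_planted_trna, len(eligible))
    planted = rng.choice(len(eligible), size=n_plant, replace=False)
    for j, gi in enumerate(sorted(planted.tolist())):
        sign = 1.0 if j % 2 == 0 else -1.0
        truth.differential_trna_genes[eligible[gi]] = sign * config.planted_trna_log2fc

    tx_ids = [f"tx{i:05d}" for i in range(config.n_transcripts)]
    k = min(config.planted_set_size, config.n_transcripts // 2)
    chosen = rng.choice(config.n_transcripts, size=2 * k, replace=False)
    design_cts = design["cell_type"].tolist()
    ct_a, ct_b = design_cts[0], design_cts[-1]
    truth.specific_transcripts[ct_a] = sorted(tx_ids[i] for i in chosen[:k])
    truth.specific_transcripts[ct_b] = sorted(tx_ids[i] for i in chosen[k:])
    if config.planted_codon is not None:
        truth.biased_codons[config.planted_codon] = config.planted_codon_shift
    return truth


def simulate_chip_counts(
    annotation: list[TRNAGeneRecord],
    config: SimConfig,
    truth: GroundTruth,
) -> CountMatrix:
    """Genes x samples Pol III ChIP count matrix with a sample sheet.

    Per-gene base propensities are log-normal and shared across cell
    types; planted genes are shifted by ``planted_trna_log2fc`` between
    the contrast groups (half the effect up in group 1, half down, so the
    pool total stays balanced); replicate counts are negative-binomial at
    ``library_depth`` expected tRNA-mapped reads per sample.
    """
    if not annotation:
        raise ValueError("empty annotation")
    config.validate()
    rng = _stream(config.seed, "chip_counts")
    design = cell_type_design(config)
    genes = [r.name for r in annotation]
    n_genes = len(genes)

    base = rng.lognormal(mean=0.0, sigma=config.expression_logsd, size=n_genes)
    silent = inactive_gene_set(annotation, config)
    for gi, g in enumerate(genes):
        if g in silent:
            base[gi] *= _INACTIVE_SCALE
    # scale to depth once, before planting, so planted multipliers carry
    # through to expected counts undistorted
    base = base / base.sum() * config.library_depth
    g1, g2 = truth.contrast_cell_types or ([], [])
    mean_by_ct = {}
    for _, row in design.iterrows():
        ct = row["cell_type"]
        mu = base.copy()
        if config.cell_type_jitter_sd > 0:
            mu = mu * rng.lognormal(0.0, config.cell_type_jitter_sd, size=n_genes)
        for gname, lfc in truth.differential_trna_genes.items():
            gi = genes.index(gname)
            if ct in g1:
                mu[gi] *= 2.0 ** (lfc / 2.0)
            elif ct in g2:
                mu[gi] *= 2.0 ** (-lfc / 2.0)
        mean_by_ct[ct] = mu

    for gname in truth.differential_trna_genes:
        gi = genes.index(gname)
        if any(mean_by_ct[ct][gi] < 1.0 for ct in mean_by_ct):
            log.warning("planted gene %s has expected count < 1 at this depth",
                        gname)
            truth.underpowered_trna_genes.append(gname)

    cols, data, sheet_rows = [], [], []
    phi = config.nb_dispersion
    for _, row in design.iterrows():
        ct = row["cell_type"]
        for rep in range(1, config.n_replicates_per_cell_type + 1):
            mu = mean_by_ct[ct]
            if phi > 0:
                lam = rng.gamma(shape=1.0 / phi, scale=phi * mu)
            else:
                lam = mu
            counts = rng.poisson(lam)
            sample = f"{ct}_r{rep}"
            cols.append(sample)
            data.append(counts)
            sheet_rows.append((sample, ct, rep, row["group"], row["class"]))

    counts_df = pd.DataFrame(
        np.column_stack(data), index=genes, columns=cols, dtype=np.int64)
    sheet = pd.DataFrame(
        sheet_rows, columns=["sample", "cell_type", "replicate", "group", "class"]
    ).set_index("sample")
    return CountMatrix(counts_df, sheet, annotation={r.name: r for r in annotation})


def _codon_freqs(config: SimConfig, rng: np.random.Generator) -> np.ndarray:
    """Shared base frequency over the 61 sense codons (Dirichlet draw)."""
    return rng.dirichlet(np.full(61, 5.0))


def _biased_freqs(base: np.ndarray, codon: str, shift: float) -> np.ndarray:
    """Raise one codon's relative frequency by ``shift`` and renormalise
    the rest proportionally."""
    i = SENSE_INDEX[codon]
    target = base[i] + shift
    if target >= 1.0:
        raise ConfigError("planted_codon_shift pushes frequency above 1")
    out = base * (1.0 - target) / (1.0 - base[i])
    out[i] = target
    return out


def simulate_translatome(
    config: SimConfig, truth: GroundTruth
) -> tuple[dict[str, str], pd.DataFrame]:
    """CDS sequences and a TPM table with planted structure.

    Every CDS is ATG + sense-codon body + one terminal stop (so no
    internal stops, length a multiple of 3).  Codons of non-planted
    transcripts follow a shared base frequency; the planted set's
    frequency of ``planted_codon`` is raised by ``planted_codon_shift``.
    TPM columns are log-normal per cell type and renormalised to 1e6 per
    sample; cell-type-specific transcripts get >= ``specificity_fold``
    TPM separation between the designated cell types (imposed before
    renormalisation; realised post-normalisation ratios are recorded in
    the ground truth).
    """
    config.validate()
    rng = _stream(config.seed, "translatome")
    n = config.n_transcripts
    tx_ids = [f"tx{i:05d}" for i in range(n)]
    base = _codon_freqs(config, rng)

    planted_set: set[str] = set()
    if truth.biased_codons:
        ct_a = next(iter(truth.specific_transcripts))
        planted_set = set(truth.specific_transcripts[ct_a])
    biased = base
    for codon, shift in truth.biased_codons.items():
        biased = _biased_freqs(biased, codon, shift)

    codon_arr = np.array(list(SENSE_CODONS))
    stop_arr = np.array(list(STOP_CODONS))
    lo, hi = config.cds_length_codons
    lengths = rng.integers(lo, hi + 1, size=n)
    cds: dict[str, str] = {}
    for i, tid in enumerate(tx_ids):
        freqs = biased if tid in planted_set else base
        body = rng.choice(61, size=lengths[i] - 1, p=freqs)
        stop = stop_arr[rng.integers(0, 3)]
        cds[tid] = "ATG" + "".join(codon_arr[body]) + str(stop)

    design = cell_type_design(config)
    fold = config.specificity_fold
    margin = np.sqrt(2.0)  # headroom so renormalisation keeps ratios >= fold
    # one shared expression level per transcript, modulated per cell type:
    # translatomes of different cell types are highly correlated, so large
    # fold differences arise only where they are planted
    shared = rng.lognormal(0.0, config.tpm_logsd, size=n)
    base_expr = {}
    spec_cts = list(truth.specific_transcripts)
    for ct in design["cell_type"]:
        base_expr[ct] = shared * rng.lognormal(
            0.0, config.tpm_celltype_sd, size=n)
    if len(spec_cts) >= 2:
        ct_a, ct_b = spec_cts[0], spec_cts[1]
        ia = [tx_ids.index(t) for t in truth.specific_transcripts[ct_a]]
        ib = [tx_ids.index(t) for t in truth.specific_transcripts[ct_b]]
        # pin the depleted side to the enriched side's draw so every
        # specific transcript has a deterministic fold * margin^2 ratio
        # before renormalisation (independent draws would wash it out)
        ratio = fold * margin**2
        base_expr[ct_b][ia] = base_expr[ct_a][ia] / ratio
        base_expr[ct_a][ib] = base_expr[ct_b][ib] / ratio

    cols, data = [], []
    for ct in design["cell_type"]:
        for rep in range(1, config.n_tpm_replicates + 1):
            vals = base_expr[ct] * rng.lognormal(0.0, 0.1, size=n)
            vals = vals / vals.sum() * 1e6
            cols.append(f"{ct}_rb{rep}")
            data.append(vals)
    tpm = pd.DataFrame(np.column_stack(data), index=tx_ids, columns=cols)

    if len(spec_cts) >= 2:
        ct_a, ct_b = spec_cts[0], spec_cts[1]
        mean_a = tpm[[c for c in cols if c.startswith(f"{ct_a}_rb")]].mean(axis=1)
        mean_b = tpm[[c for c in cols if c.startswith(f"{ct_b}_rb")]].mean(axis=1)
        for ct, other_mean, own_mean in ((ct_a, mean_b, mean_a),
                                         (ct_b, mean_a, mean_b)):
            truth.realized_specificity[ct] = {
                t: float((own_mean[t] + 1e-12) / (other_mean[t] + 1e-12))
                for t in truth.specific_transcripts[ct]
            }
    return cds, tpm


@dataclass
class SimulatedStudy:
    config: SimConfig
    annotation: list[TRNAGeneRecord]
    truth: GroundTruth
    chip: CountMatrix
    cds: dict[str, str]
    tpm: pd.DataFrame


def simulate_study(config: SimConfig | None = None) -> SimulatedStudy:
    """Generate a full synthetic study (catalogue, ChIP counts, translatome)."""
    config = config or SimConfig()
    annotation = generate_trna_annotation(config)
    truth = make_ground_truth(annotation, config)
    chip = simulate_chip_counts(annotation, config, truth)
    cds, tpm = simulate_translatome(config, truth)
    return SimulatedStudy(config, annotation, truth, chip, cds, tpm)
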