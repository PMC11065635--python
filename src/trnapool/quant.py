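"""tRNA pool quantification from Pol III ChIP-seq read counts.

Pol III ChIP-seq read density over a tRNA locus is a proxy for its
transcription.  Given a gene x sample count matrix and a gtRNAdb-style
annotation, this module produces:

* occupancy calls (a gene is "expressed" in a cell type if every replicate
  has strictly more than ``min_reads`` reads over the locus),
* relative expression: each gene's fraction of all tRNA-mapped reads in a
  sample, averaged over replicates to give cell-type levels,
* aggregation to isoacceptor families (shared anticodon), isotypes (shared
  amino acid) and transcript groups (identical mature sequence),
* within-family composition and the >5%-contributor diversity metric.

Genes annotated as tRX (ambiguous isotype/anticodon) are excluded before
normalisation, mirroring standard practice for gtRNAdb catalogues.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

Resolution = Literal["gene", "transcript_group", "isoacceptor", "isotype"]


class TRNANameError(ValueError):
    """A tRNA gene name that does not follow the gtRNAdb dialect."""


@dataclass(frozen=True)
class TRNAGeneRecord:
    """One tRNA gene with its parsed identity.

    ``transcript_group`` numbers genes whose mature tRNA sequences are
    identical (e.g. Ile-TAT-2-{1,2,3} share group 2); ``copy`` distinguishes
    the genomic copies within a group.
    """

    name: str
    isotype: str
    anticodon: str
    transcript_group: int
    copy: int
    is_trx: bool = False
    is_high_confidence: bool = True
    chrom: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None

    @property
    def isoacceptor(self) -> str:
        return f"{self.isotype}-{self.anticodon}"

    @property
    def group_id(self) -> str:
        return f"{self.isotype}-{self.anticodon}-{self.transcript_group}"


# accepts "tRNA-Ile-TAT-2-1", "Ile-TAT-2-1", "tRX-NNN-1-1", "tRNA-iMet-CAT-1-1"
_NAME_RE = re.compile(
    r"^(?:tRNA-)?(?P<iso>[A-Za-z]{1,4})-(?P<ac>[ACGTN?]{3}|\?\?\?)"
    r"-(?P<group>\d+)-(?P<copy>\d+)$"
)
_TRX_RE = re.compile(
    r"^(?:tRNA-)?(?:tRX|TRX|Und|Sup)[-]?(?P<rest>[A-Za-z?N]{0,4})"
    r"-?(?P<ac>[ACGTN?]{3})?-(?P<group>\d+)-(?P<copy>\d+)$"
)
_DASHES = str.maketrans({"–": "-", "—": "-", "‐": "-", "‑": "-"})


def parse_trna_gene_name(name: str) -> TRNAGeneRecord:
    """Parse a gtRNAdb-style tRNA gene name.

    Accepts the dialects with or without the leading ``tRNA-`` prefix and
    with en-dash separators (as typeset in journals), normalised to ASCII
    hyphens.  Genes named with the tRX prefix (ambiguous identity) are
    flagged ``is_trx`` so downstream quantification can drop them.

    >>> parse_trna_gene_name("tRNA-Ile-TAT-2-1").isoacceptor
    'Ile-TAT'
    """
    if not name or not name.strip():
        raise TRNANameError("empty tRNA gene name")
    norm = name.strip().translate(_DASHES)
    m = _TRX_RE.match(norm)
    if m and (norm.lower().startswith("trx") or "-trx-" in norm.lower()
              or norm.lower().startswith("trna-trx")):
        return TRNAGeneRecord(
            name=norm,
            isotype="tRX",
            anticodon=m.group("ac") or "NNN",
            transcript_group=int(m.group("group")),
            copy=int(m.group("copy")),
            is_trx=True,
        )
    m = _NAME_RE.match(norm)
    if m is None:
        raise TRNANameError(f"cannot parse tRNA gene name {name!r}")
    iso, ac = m.group("iso"), m.group("ac")
    is_trx = iso.lower() == "trx" or "N" in ac or "?" in ac
    return TRNAGeneRecord(
        name=norm,
        isotype=iso,
        anticodon=ac,
        transcript_group=int(m.group("group")),
        copy=int(m.group("copy")),
        is_trx=is_trx,
    )


@dataclass
class CountMatrix:
    """Non-negative integer read counts, genes x samples, plus sample sheet.

    ``sample_sheet`` is indexed by sample id with columns ``cell_type``,
    ``replicate``, ``group`` and ``class`` (neuronal / non_neuronal).
    """

    counts: pd.DataFrame
    sample_sheet: pd.DataFrame
    annotation: dict[str, TRNAGeneRecord] | None = None

    def __post_init__(self) -> None:
        if (self.counts.values < 0).any():
            raise ValueError("counts must be non-negative")
        missing = set(self.counts.columns) - set(self.sample_sheet.index)
        if missing:
            raise ValueError(f"samples missing from sample sheet: {sorted(missing)}")
        self.sample_sheet = self.sample_sheet.loc[list(self.counts.columns)]

    @property
    def genes(self) -> list[str]:
        return list(self.counts.index)

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def cell_types(self) -> list[str]:
        seen: list[str] = []
        for ct in self.sample_sheet["cell_type"]:
            if ct not in seen:
                seen.append(ct)
        return seen

    def samples_of(self, cell_type: str) -> list[str]:
        sheet = self.sample_sheet
        return list(sheet.index[sheet["cell_type"] == cell_type])

    def records(self) -> dict[str, TRNAGeneRecord]:
        if self.annotation is not None:
            return self.annotation
        return {g: parse_trna_gene_name(g) for g in self.genes}


@dataclass
class FamilyExpressionTable:
    """Relative tRNA levels (fractions of total tRNA-mapped reads).

    ``values`` holds per-sample fractions (units x samples); cell-type
    levels are the mean of the replicate fractions, so each replicate
    carries equal weight regardless of sequencing depth.
    """

    resolution: Resolution
    values: pd.DataFrame
    sample_sheet: pd.DataFrame

    def cell_type_levels(self) -> pd.DataFrame:
        """Mean replicate fraction per (unit, cell type)."""
        groups = self.sample_sheet.loc[list(self.values.columns), "cell_type"]
        out = self.values.T.groupby(groups, sort=False).mean().T
        return out

    def cell_type_sd(self) -> pd.DataFrame:
        groups = self.sample_sheet.loc[list(self.values.columns), "cell_type"]
        return self.values.T.groupby(groups, sort=False).std(ddof=1).T

    def tidy(self) -> pd.DataFrame:
        """Long-format table keyed by (unit, cell_type) with value, n, sd."""
        groups = self.sample_sheet.loc[list(self.values.columns), "cell_type"]
        n = self.values.T.groupby(groups, sort=False).count().T
        long = pd.concat(
            {"value": self.cell_type_levels().stack(),
             "n_replicates": n.stack(),
             "sd": self.cell_type_sd().stack()},
            axis=1,
        )
        long.index.names = ["unit", "cell_type"]
        return long.reset_index()


def classify_expressed(
    counts: CountMatrix, min_reads: int = 2
) -> tuple[pd.DataFrame, pd.Series]:
    """Occupancy calls: gene expressed in a cell type iff count > ``min_reads``
    in *every* replicate of that cell type (strict inequality).

    Returns the per-(gene, cell type) boolean matrix and a per-gene
    "expressed in at least one cell type" series.
    """
    per_ct = {}
    for ct in counts.cell_types:
        cols = counts.samples_of(ct)
        if len(cols) < 2:
            log.warning(
                "cell type %r has a single replicate; occupancy rule "
                "degenerates to that one sample", ct,
            )
        per_ct[ct] = (counts.counts[cols] > min_reads).all(axis=1)
    table = pd.DataFrame(per_ct)
    return table, table.any(axis=1)


def _excluded_genes(
    counts: CountMatrix, exclude_trx: bool, exclude_low_confidence: bool
) -> list[str]:
    recs = counts.records()
    out = []
    for g in counts.genes:
        r = recs.get(g)
        if r is None:
            continue
        if exclude_trx and r.is_trx:
            out.append(g)
        elif exclude_low_confidence and not r.is_high_confidence:
            out.append(g)
    return out


def relative_expression(
    counts: CountMatrix,
    exclude_trx: bool = True,
    exclude_low_confidence: bool = False,
) -> FamilyExpressionTable:
    """Per-sample gene fractions of total tRNA-mapped reads.

    value(g, s) = count(g, s) / sum over included genes of count(., s).
    tRX (and optionally low-confidence) genes are dropped *before*
    normalisation; the excluded names are logged for audit.
    """
    dropped = _excluded_genes(counts, exclude_trx, exclude_low_confidence)
    if dropped:
        log.info("excluded %d genes before normalisation: %s",
                 len(dropped), ", ".join(dropped[:10]) + ("..." if len(dropped) > 10 else ""))
    kept = counts.counts.drop(index=dropped)
    totals = kept.sum(axis=0)
    zero = totals.index[totals == 0]
    if len(zero):
        raise ValueError(f"sample(s) with zero total tRNA-mapped reads: {list(zero)}")
    fractions = kept.div(totals, axis=1)
    return FamilyExpressionTable("gene", fractions, counts.sample_sheet)


def _unit_key(rec: TRNAGeneRecord, level: Resolution) -> str:
    if level == "isoacceptor":
        return rec.isoacceptor
    if level == "isotype":
        return rec.isotype
    if level == "transcript_group":
        return rec.group_id
    return rec.name


def aggregate(
    table: FamilyExpressionTable,
    level: Resolution,
    annotation: Mapping[str, TRNAGeneRecord] | None = None,
) -> FamilyExpressionTable:
    """Sum gene-level fractions into isoacceptor / isotype / transcript-group
    units.  Aggregation is linear, so per-sample totals are conserved."""
    if table.resolution != "gene":
        raise ValueError("aggregate expects a gene-resolution table")
    recs = annotation or {g: parse_trna_gene_name(g) for g in table.values.index}
    keys = [_unit_key(recs[g], level) for g in table.values.index]
    agg = table.values.groupby(keys, sort=True).sum()
    return FamilyExpressionTable(level, agg, table.sample_sheet)


def family_composition(
    table: FamilyExpressionTable,
    annotation: Mapping[str, TRNAGeneRecord] | None = None,
    by: Resolution = "isoacceptor",
) -> pd.DataFrame:
    """Within-family fraction of each gene: value(g) / family total.

    Families with a zero total in a sample are reported as NaN (undefined),
    never as zeros — a silent 0 would fabricate a composition.
    """
    if table.resolution != "gene":
        raise ValueError("family_composition expects a gene-resolution table")
    recs = annotation or {g: parse_trna_gene_name(g) for g in table.values.index}
    keys = pd.Series([_unit_key(recs[g], by) for g in table.values.index],
                     index=table.values.index)
    fam_tot = table.values.groupby(keys.values, sort=False).transform("sum")
    with np.errstate(invalid="ignore", divide="ignore"):
        comp = table.values / fam_tot
    comp[fam_tot == 0] = np.nan
    comp.insert(0, "family", keys)
    return comp


def diversity_fraction(
    composition: pd.DataFrame, threshold: float = 0.05
) -> tuple[pd.Series, pd.DataFrame]:
    """Fraction of tRNA genes that contribute significantly (> threshold,
    strictly) to their isoacceptor family pool, per sample/cell type.

    Returns (overall contributor fraction per column, per-family contributor
    counts).  NaN compositions (zero-total families) never count.
    """
    if not 0 < threshold < 1:
        raise ValueError("threshold must be in (0, 1)")
    fam = composition["family"]
    frac = composition.drop(columns="family")
    contrib = frac > threshold  # NaN > t is False
    overall = contrib.sum(axis=0) / frac.notna().sum(axis=0)
    per_family = contrib.groupby(fam.values, sort=True).sum()
    return overall, per_family


def collapse_identical(
    counts: CountMatrix, annotation: Mapping[str, TRNAGeneRecord] | None = None
) -> CountMatrix:
    """Sum counts of genes with identical mature sequences (shared
    transcript group), e.g. Ile-TAT-2-{1,2,3} -> Ile-TAT-2.  Column totals
    are preserved exactly."""
    recs = annotation or counts.records()
    keys = [recs[g].group_id if not recs[g].is_trx else recs[g].name
            for g in counts.genes]
    collapsed = counts.counts.groupby(keys, sort=True).sum()
    return CountMatrix(collapsed, counts.sample_sheet.copy())
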