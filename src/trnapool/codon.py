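"""Expression-weighted codon usage and tRNA supply vs codon demand.

Codon demand of a cell type is estimated from its translatome: the codon
counts of every protein-coding CDS are weighted by the transcript's
expression (TPM), summed, and normalised over the 61 sense codons to
percentages.  tRNA supply is the relative level of each isoacceptor family
(from :mod:`trnapool.quant`).  The two meet in

* the codon-anticodon rank correlation, restricted to Watson-Crick pairs
  (a family's cognate codon is the exact reverse complement of its
  anticodon; codons reached only by wobble decoding are omitted), and
* the supply/demand ratio: family level (%) / cognate codon usage (%).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .genetic_code import (
    CODON_TO_AA3,
    SENSE_CODONS,
    SENSE_INDEX,
    STOP_CODONS,
    anticodon_to_codon,
)

log = logging.getLogger(__name__)

_BASE_CODE = np.full(128, -1, dtype=np.int64)
for _i, _b in enumerate(b"ACGT"):
    _BASE_CODE[_b] = _i
_CODON_OF_CODE = np.full(64, -1, dtype=np.int64)  # 16a+4b+c -> sense index
_STOP_CODES = set()
for _c in SENSE_CODONS:
    _CODON_OF_CODE[16 * _BASE_CODE[ord(_c[0])] + 4 * _BASE_CODE[ord(_c[1])]
                   + _BASE_CODE[ord(_c[2])]] = SENSE_INDEX[_c]
for _c in STOP_CODONS:
    _STOP_CODES.add(int(16 * _BASE_CODE[ord(_c[0])] + 4 * _BASE_CODE[ord(_c[1])]
                        + _BASE_CODE[ord(_c[2])]))


class CdsPolicyError(ValueError):
    """CDS rejected under the active policy (with the reason)."""


def codon_counts(
    cds: str, policy: Literal["reject", "tolerate"] = "reject"
) -> np.ndarray:
    """Count frame-0 sense codons in a CDS.

    Stop codons are excluded from the counts; a single terminal stop is
    tolerated.  Under the default ``reject`` policy a CDS whose length is
    not a multiple of 3, or that contains an internal stop or a non-ACGT
    base, raises :class:`CdsPolicyError` naming the reason; ``tolerate``
    counts whatever complete sense codons are present.

    Returns a length-61 integer vector in :data:`SENSE_CODONS` order.
    """
    if len(cds) < 3:
        raise CdsPolicyError("CDS shorter than one codon")
    arr = np.frombuffer(cds.upper().encode("ascii"), dtype=np.uint8)
    if len(arr) % 3 != 0:
        if policy == "reject":
            raise CdsPolicyError("length not multiple of 3")
        arr = arr[: 3 * (len(arr) // 3)]
    base = _BASE_CODE[arr]
    if (base < 0).any():
        if policy == "reject":
            raise CdsPolicyError("non-ACGT base in CDS")
        bad = base < 0
        base = base.copy()
        base[bad] = 0
        codes = base.reshape(-1, 3) @ np.array([16, 4, 1])
        codes = codes[~bad.reshape(-1, 3).any(axis=1)]
    else:
        codes = base.reshape(-1, 3) @ np.array([16, 4, 1])
    stop_mask = np.isin(codes, list(_STOP_CODES))
    if stop_mask[:-1].any() and policy == "reject":
        raise CdsPolicyError("internal stop")
    codes = codes[~stop_mask]
    counts = np.bincount(_CODON_OF_CODE[codes], minlength=61)
    return counts


def codon_count_matrix(
    cds_by_id: Mapping[str, str], policy: Literal["reject", "tolerate"] = "reject"
) -> tuple[pd.DataFrame, dict[str, str]]:
    """Codon counts for many transcripts; returns (matrix, rejections).

    Rejected transcripts (under ``reject``) are excluded from the matrix and
    listed with their reason instead of raising, so one bad CDS does not
    abort a translatome.
    """
    rows, ids, rejected = [], [], {}
    for tid, cds in cds_by_id.items():
        try:
            rows.append(codon_counts(cds, policy=policy))
            ids.append(tid)
        except CdsPolicyError as e:
            rejected[tid] = str(e)
    if rejected:
        log.info("rejected %d transcripts: %s", len(rejected),
                 dict(list(rejected.items())[:5]))
    mat = pd.DataFrame(np.vstack(rows) if rows else np.empty((0, 61), int),
                       index=ids, columns=list(SENSE_CODONS))
    return mat, rejected


def longest_cds_per_gene(
    cds_by_id: Mapping[str, str], gene_of: Mapping[str, str]
) -> dict[str, str]:
    """Keep the longest CDS per gene (the longest-peptide rule);
    ties broken by transcript id for determinism."""
    best: dict[str, str] = {}
    for tid in sorted(cds_by_id):
        g = gene_of.get(tid, tid)
        if g not in best or len(cds_by_id[tid]) > len(cds_by_id[best[g]]):
            best[g] = tid
    return {t: cds_by_id[t] for t in sorted(best.values())}


@dataclass
class CodonUsageVector:
    """Relative usage of the 61 sense codons, percentages summing to 100."""

    usage: pd.Series  # index = SENSE_CODONS, values = percentages
    context: str = ""
    n_transcripts: int = 0

    def __post_init__(self) -> None:
        self.usage = self.usage.reindex(list(SENSE_CODONS))
        total = float(self.usage.sum())
        if not np.isclose(total, 100.0, atol=1e-6):
            raise ValueError(f"usage must sum to 100, got {total}")

    def tidy(self) -> pd.DataFrame:
        return pd.DataFrame({
            "codon": self.usage.index,
            "amino_acid": [CODON_TO_AA3[c] for c in self.usage.index],
            "usage_pct": self.usage.values,
            "context": self.context,
        })


def weighted_codon_usage(
    codon_matrix: pd.DataFrame,
    tpm: pd.Series,
    context: str = "",
    min_tpm: float = 0.0,
) -> CodonUsageVector:
    """Expression-weighted codon usage of a transcript set.

    usage(c) = 100 * sum_t count_t(c) * tpm_t / sum_{c'} sum_t count_t(c') * tpm_t

    Transcripts with tpm <= ``min_tpm`` contribute nothing (default: all
    transcripts with tpm > 0 count).  Invariant to rescaling all TPMs by a
    constant.
    """
    tpm = tpm.reindex(codon_matrix.index).fillna(0.0)
    if (tpm < 0).any():
        raise ValueError("negative TPM")
    w = tpm.to_numpy(dtype=float)
    if min_tpm > 0:
        w = np.where(w > min_tpm, w, 0.0)
    weighted = codon_matrix.to_numpy(dtype=float).T @ w
    total = weighted.sum()
    if total <= 0:
        raise ValueError("all transcripts have zero TPM (or zero codons)")
    return CodonUsageVector(
        pd.Series(100.0 * weighted / total, index=codon_matrix.columns),
        context=context,
        n_transcripts=int((w > 0).sum()),
    )


def specific_gene_sets(
    tpm_a: pd.Series,
    tpm_b: pd.Series,
    fold: float = 50.0,
    pseudo: float = 0.01,
) -> tuple[set[str], set[str]]:
    """Cell-type-specific transcripts: >= ``fold``-fold mean TPM difference.

    set_A holds transcripts with (tpm_a + pseudo)/(tpm_b + pseudo) >= fold,
    and symmetrically for set_B; the sets are disjoint by construction for
    fold > 1.
    """
    universe = tpm_a.index.intersection(tpm_b.index)
    a = tpm_a.loc[universe].to_numpy(dtype=float) + pseudo
    b = tpm_b.loc[universe].to_numpy(dtype=float) + pseudo
    set_a = set(universe[a / b >= fold])
    set_b = set(universe[b / a >= fold])
    return set_a, set_b


@dataclass
class SupplyDemandRecord:
    isoacceptor: str
    cognate_codon: str
    trna_level: float  # % of total tRNA pool
    codon_usage: float  # % of total sense-codon usage
    ratio: float


def supply_demand_ratio(
    isoacceptor_levels: pd.Series,
    usage: CodonUsageVector,
) -> pd.DataFrame:
    """tRNA supply / codon demand per isoacceptor family.

    ``isoacceptor_levels`` are family fractions (summing to 1) or
    percentages (summing to 100) indexed by "Iso-ANT" family names; they are
    reported as percentages.  The ratio is level% / cognate-codon usage%;
    a zero codon usage is an error, never an infinite ratio.  Families whose
    reverse-complement "codon" is a stop have no Watson-Crick cognate and
    get a NaN ratio with a reason.
    """
    levels = isoacceptor_levels.astype(float)
    if np.isclose(levels.sum(), 1.0, atol=1e-6):
        levels = levels * 100.0
    rows = []
    for fam, level in levels.items():
        anticodon = str(fam).rsplit("-", 1)[-1]
        codon = anticodon_to_codon(anticodon)
        if codon not in SENSE_INDEX:
            rows.append((fam, codon, level, np.nan, np.nan, "cognate codon is a stop"))
            continue
        u = float(usage.usage[codon])
        if u == 0.0:
            raise ValueError(f"zero usage for cognate codon {codon} of {fam}")
        rows.append((fam, codon, level, u, level / u, ""))
    return pd.DataFrame(
        rows,
        columns=["isoacceptor", "cognate_codon", "trna_pct", "codon_pct",
                 "ratio", "note"],
    ).set_index("isoacceptor")


def codon_anticodon_correlation(
    isoacceptor_levels: pd.Series,
    usage: CodonUsageVector,
    min_pairs: int = 3,
) -> tuple[float, pd.DataFrame]:
    """Spearman rank correlation between isoacceptor family levels and the
    usage of their Watson-Crick cognate codons.

    Only exact reverse-complement pairs enter: families whose cognate is a
    stop codon, and sense codons decoded solely by wobble (no expressed
    family with the exact anticodon), are excluded and recorded in the pair
    table with the reason "wobble-only decoding".  Ties get average ranks.
    """
    levels = isoacceptor_levels.astype(float)
    if np.isclose(levels.sum(), 1.0, atol=1e-6):
        levels = levels * 100.0
    fam_of_codon: dict[str, str] = {}
    rows = []
    for fam, level in levels.items():
        anticodon = str(fam).rsplit("-", 1)[-1]
        codon = anticodon_to_codon(anticodon)
        if codon not in SENSE_INDEX:
            rows.append((fam, codon, level, np.nan, False, "cognate codon is a stop"))
        elif level <= 0:
            rows.append((fam, codon, level, float(usage.usage[codon]), False,
                         "family not expressed"))
        else:
            fam_of_codon[codon] = fam
            rows.append((fam, codon, level, float(usage.usage[codon]), True, ""))
    for codon in SENSE_CODONS:
        if codon not in fam_of_codon:
            has_row = any(r[1] == codon for r in rows)
            if not has_row:
                rows.append(("", codon, np.nan, float(usage.usage[codon]), False,
                             "wobble-only decoding"))
    pairs = pd.DataFrame(
        rows, columns=["isoacceptor", "codon", "trna_pct", "codon_pct",
                       "included", "exclusion_reason"],
    )
    included = pairs[pairs["included"]]
    if len(included) < min_pairs:
        raise ValueError(
            f"only {len(included)} Watson-Crick pairs available (need >= {min_pairs})"
        )
    rho = stats.spearmanr(included["trna_pct"], included["codon_pct"]).statistic
    return float(rho), pairs


def matched_mismatched_test(rho_matrix: pd.DataFrame) -> tuple[float, float]:
    """Two-sided Mann-Whitney U comparing matched vs mismatched
    codon-anticodon correlations.

    ``rho_matrix``: rows = tRNA cell types, columns = translatome cell
    types; the diagonal (same cell type on both axes) is "matched", the
    off-diagonal "mismatched".  Returns (U, p).
    """
    if rho_matrix.shape[0] < 2 or rho_matrix.shape[1] < 2:
        raise ValueError("need at least 2 cell types on each axis")
    shared = [ct for ct in rho_matrix.index if ct in rho_matrix.columns]
    if len(shared) < 2:
        raise ValueError("need >= 2 cell types present on both axes")
    matched = np.array([rho_matrix.loc[ct, ct] for ct in shared])
    mism = []
    for r in rho_matrix.index:
        for c in rho_matrix.columns:
            if r != c:
                mism.append(rho_matrix.loc[r, c])
    mism = np.asarray(mism, dtype=float)
    pooled = np.concatenate([matched, mism])
    if np.all(pooled == pooled[0]):
        # every correlation identical: no evidence of a difference
        return float(matched.size * mism.size / 2.0), 1.0
    res = stats.mannwhitneyu(matched, mism, alternative="two-sided", method="auto")
    return float(res.statistic), float(res.pvalue)
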