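"""Empirical permutation tests for codon usage in gene sets.

Two procedures share a sampling engine that draws random transcript sets
(uniform, without replacement within a set, independent across draws):

* :func:`empirical_codon_enrichment` — for a gene set of interest, compare
  the usage of each of the 61 sense codons against the usage in random
  same-size sets drawn from the detected-transcript universe.  Two
  empirical p-values are reported per codon: the fraction of random sets
  with strictly higher usage (p_high) and strictly lower usage (p_low);
  a codon is over-represented when p_high <= alpha (few random sets beat
  it) and under-represented when p_low <= alpha.

* :func:`empirical_correlation_null` — the null distribution of the
  Pearson correlation between the usage vectors of two random sets of the
  stated sizes, used to ask whether two cell-type-specific gene sets are
  less correlated than expected by chance (p_low).

All p-values default to the plain fraction of permutations; the smoothed
(r+1)/(n+1) estimator, which can never be exactly zero and is
super-uniform under the null, is available via ``smoothed=True``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .codon import CodonUsageVector
from .genetic_code import SENSE_CODONS

_CHUNK = 500  # permutations per vectorised block (memory/speed balance)


@dataclass
class EmpiricalTestResult:
    """Observed statistic with its permutation-null placement.

    ``p_low`` / ``p_high`` / ``p_equal`` are the fractions of permutations
    strictly below / strictly above / exactly equal to the observed value;
    they are derived from integer counts, so they sum to 1 exactly.
    """

    statistic_name: str
    observed: float
    n_perm: int
    n_below: int
    n_above: int
    seed: int
    set_size: int
    universe_size: int
    smoothed: bool = False

    @property
    def n_equal(self) -> int:
        return self.n_perm - self.n_below - self.n_above

    @property
    def p_low(self) -> float:
        """Fraction of permutations strictly below the observed value."""
        if self.smoothed:
            return (self.n_below + 1) / (self.n_perm + 1)
        return self.n_below / self.n_perm

    @property
    def p_high(self) -> float:
        if self.smoothed:
            return (self.n_above + 1) / (self.n_perm + 1)
        return self.n_above / self.n_perm

    @property
    def p_equal(self) -> float:
        return self.n_equal / self.n_perm


def sample_gene_sets(
    universe_size: int,
    size: int,
    n_perm: int,
    seed: int | np.random.Generator,
):
    """Yield ``n_perm`` random index sets of ``size`` drawn uniformly
    without replacement from ``range(universe_size)``.

    Sets are independent across permutations and fully reproducible from
    the seed.  Internally permutations are drawn in vectorised blocks.
    """
    if size > universe_size:
        raise ValueError(f"set size {size} exceeds universe {universe_size}")
    rng = (seed if isinstance(seed, np.random.Generator)
           else np.random.default_rng(seed))
    remaining = n_perm
    while remaining > 0:
        block = min(remaining, _CHUNK)
        # uniform subsets: indices of the `size` smallest iid random keys;
        # sorted so identical subsets always sum in the same float order
        keys = rng.random((block, universe_size))
        idx = np.sort(np.argpartition(keys, size - 1, axis=1)[:, :size], axis=1)
        for row in idx:
            yield row
        remaining -= block


def _null_usage_matrix(
    weighted: np.ndarray,
    universe_size: int,
    size: int,
    n_perm: int,
    rng: np.random.Generator,
) -> np.ndarray:
    """Usage percentages (n_perm x 61) of random sets.

    ``weighted`` is the per-transcript count x TPM matrix (n x 61).
    """
    out = np.empty((n_perm, weighted.shape[1]))
    done = 0
    for idx in _index_blocks(universe_size, size, n_perm, rng):
        sums = weighted[idx].sum(axis=1)  # (block, 61)
        totals = sums.sum(axis=1, keepdims=True)
        np.divide(sums, totals, out=sums, where=totals > 0)
        out[done:done + len(idx)] = 100.0 * sums
        done += len(idx)
    return out


def _index_blocks(universe_size, size, n_perm, rng):
    remaining = n_perm
    while remaining > 0:
        block = min(remaining, _CHUNK)
        keys = rng.random((block, universe_size))
        yield np.sort(np.argpartition(keys, size - 1, axis=1)[:, :size], axis=1)
        remaining -= block


def empirical_codon_enrichment(
    codon_matrix: pd.DataFrame,
    tpm: pd.Series,
    gene_set: set[str] | list[str],
    n_perm: int = 10_000,
    seed: int = 0,
    alpha: float = 0.05,
    smoothed: bool = False,
) -> pd.DataFrame:
    """Per-codon over/under-representation of a gene set vs random sets.

    One pass of ``n_perm`` random same-size sets from the universe (the
    rows of ``codon_matrix``) serves all 61 codons.  Returns a tidy frame
    indexed by codon with observed usage, null mean, p_high, p_low and
    over/under flags at ``alpha``.
    """
    gene_set = sorted(set(gene_set))
    if not gene_set:
        raise ValueError("empty gene set")
    missing = set(gene_set) - set(codon_matrix.index)
    if missing:
        raise ValueError(f"gene set members outside universe: {sorted(missing)[:5]}")
    tpm = tpm.reindex(codon_matrix.index).fillna(0.0)
    weighted = codon_matrix.to_numpy(dtype=float) * tpm.to_numpy(dtype=float)[:, None]

    pos = codon_matrix.index.get_indexer(gene_set)
    # same op order as the null path so identical subsets tie exactly
    obs_sum = weighted[pos].sum(axis=0)
    obs = 100.0 * (obs_sum / obs_sum.sum())

    rng = np.random.default_rng(seed)
    null = _null_usage_matrix(weighted, len(codon_matrix), len(gene_set),
                              n_perm, rng)
    n_above = (null > obs).sum(axis=0)
    n_below = (null < obs).sum(axis=0)
    if smoothed:
        p_high = (n_above + 1) / (n_perm + 1)
        p_low = (n_below + 1) / (n_perm + 1)
    else:
        p_high = n_above / n_perm
        p_low = n_below / n_perm
    out = pd.DataFrame({
        "observed_pct": obs,
        "null_mean_pct": null.mean(axis=0),
        "p_high": p_high,
        "p_low": p_low,
        "n_above": n_above,
        "n_below": n_below,
        "flag_over": p_high <= alpha,
        "flag_under": p_low <= alpha,
    }, index=codon_matrix.columns)
    out.attrs.update(n_perm=n_perm, seed=seed, set_size=len(gene_set),
                     universe_size=len(codon_matrix), alpha=alpha,
                     smoothed=smoothed)
    return out


def empirical_correlation_null(
    codon_matrix: pd.DataFrame,
    tpm_a: pd.Series,
    tpm_b: pd.Series,
    set_sizes: tuple[int, int],
    observed: float | None = None,
    observed_sets: tuple[set, set] | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
    smoothed: bool = False,
) -> EmpiricalTestResult:
    """Null distribution of the Pearson correlation between the usage
    vectors of two random transcript sets.

    Each permutation draws two independent random sets of ``set_sizes``
    from the universe, computes each set's expression-weighted usage in
    its respective cell type (``tpm_a`` / ``tpm_b``), and correlates the
    two 61-vectors.  The observed correlation (either given directly or
    computed from ``observed_sets``) is placed in this null; ``p_low`` is
    the one-sided "lower than expected by chance" p-value.
    """
    from .codon import weighted_codon_usage

    if (observed is None) == (observed_sets is None):
        raise ValueError("give exactly one of observed / observed_sets")
    tpm_a = tpm_a.reindex(codon_matrix.index).fillna(0.0)
    tpm_b = tpm_b.reindex(codon_matrix.index).fillna(0.0)
    counts = codon_matrix.to_numpy(dtype=float)
    wa = counts * tpm_a.to_numpy(dtype=float)[:, None]
    wb = counts * tpm_b.to_numpy(dtype=float)[:, None]

    if observed_sets is not None:
        sa = codon_matrix.index.get_indexer(sorted(observed_sets[0]))
        sb = codon_matrix.index.get_indexer(sorted(observed_sets[1]))
        ua, ub = wa[sa].sum(axis=0), wb[sb].sum(axis=0)
        observed = float(np.corrcoef(ua / ua.sum(), ub / ub.sum())[0, 1])

    rng = np.random.default_rng(seed)
    na, nb = set_sizes
    null_a = _null_usage_matrix(wa, len(codon_matrix), na, n_perm, rng)
    null_b = _null_usage_matrix(wb, len(codon_matrix), nb, n_perm, rng)
    # row-wise Pearson correlation between paired usage vectors
    ca = null_a - null_a.mean(axis=1, keepdims=True)
    cb = null_b - null_b.mean(axis=1, keepdims=True)
    num = (ca * cb).sum(axis=1)
    den = np.sqrt((ca**2).sum(axis=1) * (cb**2).sum(axis=1))
    null_r = num / den
    return EmpiricalTestResult(
        statistic_name="pearson_usage_correlation",
        observed=float(observed),
        n_perm=n_perm,
        n_below=int((null_r < observed).sum()),
        n_above=int((null_r > observed).sum()),
        seed=int(seed) if not isinstance(seed, np.random.Generator) else -1,
        set_size=na,
        universe_size=len(codon_matrix),
        smoothed=smoothed,
    )
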