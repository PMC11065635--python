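"""Differential tRNA expression statistics.

For each unit (gene, transcript group, isoacceptor family or isotype) the
two groups' replicate-level fractions are compared with a variance-gated
two-sample t-test: a two-sided F-test first checks whether the group
variances differ; if it rejects (p_F < gate_alpha) the Welch t-test with
Satterthwaite degrees of freedom is used, otherwise the pooled-variance
Student t-test.  P-values across all units at one resolution are adjusted
with the Benjamini-Hochberg step-up procedure, and a unit is called
significant when q <= alpha and |log2 fold change| >= fc_min.

Fold changes are computed on relative fractions (the expression unit of the
whole pipeline), with a pseudocount to keep log2 ratios finite when a group
mean is zero.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .quant import FamilyExpressionTable

log = logging.getLogger(__name__)


@dataclass
class TestResult:
    unit: str
    mean1: float
    mean2: float
    log2fc: float
    t_stat: float
    df: float
    p: float
    q: float
    test_used: Literal["student", "welch", "degenerate"]
    significant: bool


def variance_gated_ttest(
    group1: Sequence[float],
    group2: Sequence[float],
    gate_alpha: float = 0.05,
) -> tuple[float, float, float, str]:
    """Two-sample t-test with an F-test variance gate.

    Returns ``(t, df, p, test_used)`` with a two-sided p-value.  Degenerate
    inputs (zero variance in both groups) fall back to the convention
    p = 1 for equal means and p = 0 for unequal means, flagged
    ``"degenerate"``.
    """
    x = np.asarray(group1, dtype=float)
    y = np.asarray(group2, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("each group needs at least 2 values")
    v1, v2 = x.var(ddof=1), y.var(ddof=1)
    if v1 == 0.0 and v2 == 0.0:
        if x.mean() == y.mean():
            return 0.0, float(x.size + y.size - 2), 1.0, "degenerate"
        log.warning("zero variance in both groups with unequal means")
        return np.inf, float(x.size + y.size - 2), 0.0, "degenerate"
    # two-sided F-test on the variance ratio
    if v2 == 0.0:
        p_f = 0.0
    else:
        f = v1 / v2
        p_f = 2.0 * min(
            stats.f.cdf(f, x.size - 1, y.size - 1),
            stats.f.sf(f, x.size - 1, y.size - 1),
        )
        p_f = min(p_f, 1.0)
    equal_var = p_f >= gate_alpha
    res = stats.ttest_ind(x, y, equal_var=equal_var)
    df = float(res.df) if hasattr(res, "df") else (
        x.size + y.size - 2 if equal_var else _welch_df(v1, v2, x.size, y.size)
    )
    return float(res.statistic), df, float(res.pvalue), (
        "student" if equal_var else "welch"
    )


def _welch_df(v1: float, v2: float, n1: int, n2: int) -> float:
    a, b = v1 / n1, v2 / n2
    return (a + b) ** 2 / (a**2 / (n1 - 1) + b**2 / (n2 - 1))


def bh_adjust(p_values: Sequence[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values),
    q_(i) = min_{j>=i}(p_(j) * m / j) capped at 1, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def differential_table(
    expr: FamilyExpressionTable,
    group1_samples: Sequence[str],
    group2_samples: Sequence[str],
    alpha: float = 0.05,
    fc_min: float = 0.5,
    gate_alpha: float = 0.05,
    pseudo: float | None = None,
) -> pd.DataFrame:
    """Differential test of every unit between two sample groups.

    ``pseudo`` defaults to half the smallest nonzero fraction in the table,
    keeping log2 fold changes finite without dominating observed values.
    Significance requires q <= alpha AND |log2fc| >= fc_min.
    """
    g1 = list(group1_samples)
    g2 = list(group2_samples)
    shared = set(g1) & set(g2)
    if shared:
        raise ValueError(f"groups share sample(s): {sorted(shared)}")
    vals = expr.values
    missing = (set(g1) | set(g2)) - set(vals.columns)
    if missing:
        raise ValueError(f"unknown sample(s): {sorted(missing)}")
    if pseudo is None:
        nz = vals.values[vals.values > 0]
        pseudo = float(nz.min()) / 2.0 if nz.size else 1e-9

    rows = []
    for unit in vals.index:
        x = vals.loc[unit, g1].to_numpy(dtype=float)
        y = vals.loc[unit, g2].to_numpy(dtype=float)
        t, df, p, used = variance_gated_ttest(x, y, gate_alpha=gate_alpha)
        m1, m2 = x.mean(), y.mean()
        rows.append((unit, m1, m2,
                     np.log2((m1 + pseudo) / (m2 + pseudo)), t, df, p, used))
    out = pd.DataFrame(
        rows,
        columns=["unit", "mean1", "mean2", "log2fc", "t", "df", "p", "test_used"],
    )
    out["q"] = bh_adjust(out["p"].to_numpy())
    out["significant"] = (out["q"] <= alpha) & (out["log2fc"].abs() >= fc_min)
    out.attrs.update(
        resolution=expr.resolution, alpha=alpha, fc_min=fc_min,
        gate_alpha=gate_alpha, pseudo=pseudo,
    )
    return out


def high_variance_genes(expr: FamilyExpressionTable, k: int = 25) -> pd.DataFrame:
    """Top-k high-variance units after the within-cell-type variance filter.

    A unit is dropped when the variance across any cell type's replicates
    exceeds (strictly) the variance of its cell-type means across cell
    types; survivors are ranked by that across-cell-type (population)
    variance, descending, ties broken by unit name for determinism.
    """
    ct_means = expr.cell_type_levels()
    if ct_means.shape[1] < 2:
        raise ValueError("need at least 2 cell types")
    pop_var = ct_means.var(axis=1, ddof=1)
    groups = expr.sample_sheet.loc[list(expr.values.columns), "cell_type"]
    within = expr.values.T.groupby(groups, sort=False).var(ddof=1).T
    keep = ~(within.gt(pop_var, axis=0).any(axis=1))
    survivors = pd.DataFrame({
        "population_variance": pop_var[keep],
        "max_within_variance": within[keep].max(axis=1),
    })
    # rank by population variance descending; ties broken by unit name
    survivors = survivors.iloc[
        np.lexsort((survivors.index.to_numpy(), -survivors["population_variance"].to_numpy()))
    ]
    if k > len(survivors):
        log.info("requested top %d but only %d units survive the variance filter",
                 k, len(survivors))
    return survivors.head(k)
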