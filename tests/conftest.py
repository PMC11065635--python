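import numpy as np
import pandas as pd
import pytest

import trnapool as tp


@pytest.fixture(scope="session")
def small_study():
    """Small synthetic study shared by read-only tests."""
    cfg = tp.SimConfig(
        seed=11,
        n_families=12,
        genes_per_family=(2, 5),
        n_identical_groups=4,
        n_cell_types=4,
        n_replicates_per_cell_type=3,
        library_depth=200_000,
        n_transcripts=200,
        cds_length_codons=(50, 200),
        planted_codon="GAA",
        planted_set_size=30,
    )
    return tp.simulate_study(cfg)


@pytest.fixture()
def toy_counts():
    """Hand-sized count matrix with two cell types, two replicates each."""
    counts = pd.DataFrame(
        {
            "A_r1": [50, 30, 10, 5, 0],
            "A_r2": [45, 35, 12, 3, 0],
            "B_r1": [10, 60, 20, 100, 2],
            "B_r2": [12, 55, 25, 95, 1],
        },
        index=[
            "tRNA-Ile-TAT-2-1",
            "tRNA-Ile-TAT-2-2",
            "tRNA-Ile-TAT-2-3",
            "tRNA-Arg-TCT-4-1",
            "tRX-NNN-1-1",
        ],
    )
    sheet = pd.DataFrame(
        {
            "cell_type": ["A", "A", "B", "B"],
            "replicate": [1, 2, 1, 2],
            "group": ["1", "1", "2", "2"],
            "class": ["neuronal"] * 4,
        },
        index=counts.columns,
    )
    return tp.CountMatrix(counts, sheet)


# ---------- independent oracles (kept deliberately naive) ----------

def brute_force_bh(p):
    """Step-up definition: q_(i) = min_{j>=i}(p_(j)*m/j), capped at 1."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q = np.empty(m)
    for pos, i in enumerate(order):
        candidates = [p[order[j]] * m / (j + 1) for j in range(pos, m)]
        q[i] = min(1.0, min(candidates))
    return q


def brute_force_weighted_usage(codon_matrix: pd.DataFrame, tpm: pd.Series):
    """Transcript-by-transcript accumulation of count x tpm."""
    acc = {c: 0.0 for c in codon_matrix.columns}
    for t in codon_matrix.index:
        w = float(tpm.get(t, 0.0))
        for c in codon_matrix.columns:
            acc[c] += float(codon_matrix.at[t, c]) * w
    total = sum(acc.values())
    return pd.Series({c: 100.0 * v / total for c, v in acc.items()})


def _avg_ranks(x):
    x = np.asarray(x, float)
    order = np.argsort(x, kind="stable")
    ranks = np.empty(len(x))
    i = 0
    sx = x[order]
    while i < len(x):
        j = i
        while j + 1 < len(x) and sx[j + 1] == sx[i]:
            j += 1
        ranks[order[i:j + 1]] = (i + j) / 2.0 + 1.0
        i = j + 1
    return ranks


def brute_force_spearman(x, y):
    """Rank (average ties) then Pearson."""
    rx, ry = _avg_ranks(x), _avg_ranks(y)
    rx = rx - rx.mean()
    ry = ry - ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx**2).sum() * (ry**2).sum()))


def brute_force_pearson(x, y):
    x = np.asarray(x, float) - np.mean(x)
    y = np.asarray(y, float) - np.mean(y)
    return float((x * y).sum() / np.sqrt((x**2).sum() * (y**2).sum()))
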