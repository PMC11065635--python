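"""Descriptive multivariate machinery: row z-scores, PCA, Euclidean
clustering with deterministic leaf order, and Gaussian fits to frequency
distributions.

Everything here is deterministic given its inputs: PCA signs follow a
fixed convention and dendrogram leaves are ordered by an explicit
smallest-subtree-first rule, so repeated runs (and tests) see identical
output.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy
from scipy.optimize import curve_fit
from scipy.spatial.distance import pdist, squareform


def zscore_rows(matrix: pd.DataFrame) -> tuple[pd.DataFrame, pd.Series]:
    """Per-row z-scores (x - mean)/sd with sample sd (ddof=1).

    Rows with zero spread cannot be standardised; they become all-zero and
    are flagged in the returned boolean series rather than silently NaN.
    """
    vals = matrix.to_numpy(dtype=float)
    if vals.shape[1] < 2:
        raise ValueError("each row needs at least 2 values")
    mean = vals.mean(axis=1, keepdims=True)
    sd = vals.std(axis=1, ddof=1, keepdims=True)
    degenerate = (sd == 0).ravel()
    safe_sd = np.where(sd == 0, 1.0, sd)
    z = (vals - mean) / safe_sd
    z[degenerate] = 0.0
    return (pd.DataFrame(z, index=matrix.index, columns=matrix.columns),
            pd.Series(degenerate, index=matrix.index, name="constant_row"))


@dataclass
class PCAResult:
    scores: pd.DataFrame       # samples x components
    loadings: pd.DataFrame     # units x components
    variance_explained: np.ndarray  # fractions, non-increasing


def pca(matrix: pd.DataFrame, scale: bool = False) -> PCAResult:
    """Centered PCA of a units x samples matrix via SVD.

    Samples are observations (columns of the input).  ``scale=True``
    additionally divides each unit by its sd (unit-variance PCA).  Sign
    convention: in every component the largest-magnitude loading is
    positive, making the decomposition reproducible across BLAS builds.
    """
    X = matrix.to_numpy(dtype=float).T  # samples x units
    if X.shape[0] < 2 or X.shape[1] < 2:
        raise ValueError("need at least 2 samples and 2 units")
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0, ddof=1)
        X = X / np.where(sd == 0, 1.0, sd)
    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    # fix signs: largest |loading| positive per component
    flip = np.sign(Vt[np.arange(Vt.shape[0]), np.abs(Vt).argmax(axis=1)])
    flip[flip == 0] = 1.0
    Vt = Vt * flip[:, None]
    U = U * flip[None, :]
    var = S**2
    frac = var / var.sum() if var.sum() > 0 else var
    comps = [f"PC{i+1}" for i in range(len(S))]
    return PCAResult(
        scores=pd.DataFrame(U * S, index=matrix.columns, columns=comps),
        loadings=pd.DataFrame(Vt.T, index=matrix.index, columns=comps),
        variance_explained=frac,
    )


def _leaf_order(Z: np.ndarray, n: int, labels: list[str]) -> list[int]:
    """Deterministic smallest-subtree-first leaf order.

    At every internal node the child with the fewer leaves comes first;
    equal-size subtrees are ordered by their smallest leaf label.
    """
    def walk(node: int) -> list[int]:
        if node < n:
            return [node]
        left, right = int(Z[node - n, 0]), int(Z[node - n, 1])
        lo, ro = walk(left), walk(right)
        lkey = (len(lo), min(labels[i] for i in lo))
        rkey = (len(ro), min(labels[i] for i in ro))
        return lo + ro if lkey <= rkey else ro + lo

    return walk(2 * n - 2)


def euclidean_ordering(
    matrix: pd.DataFrame, linkage: str = "average"
) -> tuple[pd.DataFrame, list[str]]:
    """Pairwise Euclidean distances between columns and a deterministic
    dendrogram leaf order (average linkage by default)."""
    if matrix.shape[1] < 2:
        raise ValueError("need at least 2 columns to cluster")
    X = matrix.to_numpy(dtype=float).T
    d = pdist(X, metric="euclidean")
    labels = [str(c) for c in matrix.columns]
    dist = pd.DataFrame(squareform(d), index=matrix.columns, columns=matrix.columns)
    Z = hierarchy.linkage(d, method=linkage)
    order = _leaf_order(Z, len(labels), labels)
    return dist, [labels[i] for i in order]


@dataclass
class GaussianFit:
    amplitude: float
    mean: float
    sd: float
    rss: float
    n_bins: int


def _gauss(x, a, mu, sigma):
    return a * np.exp(-((x - mu) ** 2) / (2.0 * sigma**2))


def gaussian_frequency_fit(values, bin_width: float) -> GaussianFit:
    """Histogram the values and least-squares fit a Gaussian
    A*exp(-(x-mu)^2 / (2 sigma^2)) to the bin-center counts.

    Initialisation: mu0 = sample mean, sigma0 = sample sd, A0 = max bin
    count; the fit is the frequency-distribution-plus-curve-fit recipe
    familiar from graphing software.
    """
    v = np.asarray(values, dtype=float)
    v = v[np.isfinite(v)]
    if np.unique(v).size < 5:
        raise ValueError("need at least 5 distinct values")
    lo = np.floor(v.min() / bin_width) * bin_width
    hi = np.ceil(v.max() / bin_width) * bin_width + bin_width / 2
    edges = np.arange(lo, hi + bin_width, bin_width)
    counts, edges = np.histogram(v, bins=edges)
    if (counts > 0).sum() < 2:
        raise ValueError("degenerate histogram: a single occupied bin")
    centers = (edges[:-1] + edges[1:]) / 2.0
    p0 = [float(counts.max()), float(v.mean()), float(v.std(ddof=1))]
    popt, _ = curve_fit(
        _gauss, centers, counts, p0=p0, maxfev=20_000,
        ftol=1e-8, xtol=1e-8,
    )
    a, mu, sigma = popt
    rss = float(((counts - _gauss(centers, *popt)) ** 2).sum())
    return GaussianFit(amplitude=float(a), mean=float(mu), sd=abs(float(sigma)),
                       rss=rss, n_bins=len(counts))
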