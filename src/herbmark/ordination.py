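"""Compositional beta-diversity: low-count filter, CLR, Aitchison PCA.

Counts are compositional: only relative abundances carry information, so
beta-diversity uses the centred log-ratio (CLR) transform, under which
Euclidean distance between samples is the Aitchison distance.  Rows whose
total count over all samples is below 10 (putative contamination or
chimeras) are removed first; a pseudocount handles zeros.
"""
from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

DEFAULT_MIN_TOTAL = 10
DEFAULT_PSEUDOCOUNT = 1.0


def filter_low_count(matrix: pd.DataFrame, min_total: int = DEFAULT_MIN_TOTAL) -> pd.DataFrame:
    """Drop rows (taxa) whose total count is strictly less than *min_total*;
    row order is otherwise preserved."""
    totals = matrix.sum(axis=1)
    return matrix.loc[totals >= min_total]


def clr_transform(matrix: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT) -> pd.DataFrame:
    """Centred log-ratio per sample column: x_i -> ln((c_i + p) / g), with g
    the geometric mean of (c + p) over taxa.  Columns sum to zero."""
    if pseudocount <= 0:
        raise ValueError("pseudocount must be positive")
    x = matrix.to_numpy(dtype=float) + pseudocount
    logx = np.log(x)
    clr = logx - logx.mean(axis=0, keepdims=True)
    return pd.DataFrame(clr, index=matrix.index, columns=matrix.columns)


def aitchison_distances(
    matrix: pd.DataFrame, pseudocount: float = DEFAULT_PSEUDOCOUNT
) -> pd.DataFrame:
    """Pairwise Aitchison distances between samples (Euclidean on CLR)."""
    clr = clr_transform(matrix, pseudocount)
    d = squareform(pdist(clr.to_numpy().T, metric="euclidean"))
    return pd.DataFrame(d, index=matrix.columns, columns=matrix.columns)


@dataclass
class OrdinationResult:
    """PCA of CLR-transformed counts.

    ``scores`` is samples x axes; ``variance_fractions`` are non-negative,
    non-increasing and sum to 1 when all axes are kept.
    """

    scores: pd.DataFrame
    variance_fractions: np.ndarray
    taxa: list[str]
    pseudocount: float


def pca(clr_matrix: pd.DataFrame, n_axes: int | None = None,
        pseudocount: float = DEFAULT_PSEUDOCOUNT) -> OrdinationResult:
    """PCA via eigendecomposition of the taxon covariance of CLR samples.

    Samples are observations (columns of *clr_matrix*), taxa are features.
    Each axis is oriented so its largest-magnitude loading is positive,
    making the result deterministic.
    """
    n_taxa, n_samples = clr_matrix.shape
    if n_samples < 2 or n_taxa < 2:
        raise ValueError("need at least 2 samples and 2 taxa")
    X = clr_matrix.to_numpy(dtype=float).T  # samples x taxa
    Xc = X - X.mean(axis=0, keepdims=True)
    cov = (Xc.T @ Xc) / (n_samples - 1)
    eigvals, eigvecs = np.linalg.eigh(cov)
    order = np.argsort(eigvals)[::-1]
    eigvals = np.clip(eigvals[order], 0.0, None)
    eigvecs = eigvecs[:, order]
    if n_axes is None:
        n_axes = n_taxa
    eigvals_kept = eigvals[:n_axes]
    V = eigvecs[:, :n_axes]
    # sign convention: largest-|loading| entry positive per axis
    for a in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, a])))
        if V[i, a] < 0:
            V[:, a] = -V[:, a]
    scores = Xc @ V
    total = eigvals.sum()
    fractions = eigvals_kept / total if total > 0 else np.zeros(n_axes)
    axes = [f"PC{i + 1}" for i in range(n_axes)]
    return OrdinationResult(
        scores=pd.DataFrame(scores, index=clr_matrix.columns, columns=axes),
        variance_fractions=fractions,
        taxa=list(clr_matrix.index),
        pseudocount=pseudocount,
    )


def ordinate(
    matrix: pd.DataFrame,
    min_total: int = DEFAULT_MIN_TOTAL,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    n_axes: int | None = None,
) -> OrdinationResult:
    """Filter low-count rows, CLR-transform and run PCA in one call."""
    filtered = filter_low_count(matrix, min_total)
    clr = clr_transform(filtered, pseudocount)
    return pca(clr, n_axes=n_axes, pseudocount=pseudocount)


def plot_scores(result: OrdinationResult, path: str | Path, axes: tuple[int, int] = (0, 1)) -> None:
    """Optional 2-D scatter of sample scores."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    a, b = axes
    fig, ax = plt.subplots(figsize=(6, 5))
    xs = result.scores.iloc[:, a]
    ys = result.scores.iloc[:, b]
    ax.scatter(xs, ys)
    for sample, x, y in zip(result.scores.index, xs, ys):
        ax.annotate(str(sample), (x, y), fontsize=7)
    ax.set_xlabel(f"PC{a + 1} ({result.variance_fractions[a] * 100:.2f}%)")
    ax.set_ylabel(f"PC{b + 1} ({result.variance_fractions[b] * 100:.2f}%)")
    ax.set_title("Aitchison PCA of sample compositions")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
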