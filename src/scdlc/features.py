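"""BW (between/within sum-of-squares) gene ranking.

For gene j with K classes of sizes n_k, class means xbar_k.j and grand
mean xbar_..j defined as the *unweighted* average of class means,

    BW(j) = sum_k sum_{i=1..n_k} (xbar_k.j - xbar_..j)^2
            -----------------------------------------------
            sum_k sum_{i=1..n_k} (x_kij  - xbar_..j)^2

i.e. the denominator is the total sum of squares about the grand mean.
The classic Dudoit-style variant with a true within-class denominator
sum_k sum_i (x_kij - xbar_k.j)^2 is available via ``denominator="within"``.

Scores are computed by default on the same preprocessed expression scale
the network consumes (median-depth normalization + log1p), so ranking and
model see identical values; ``scale="raw"`` ranks on raw counts.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .network import log_normalize
from .simulate import ClassLabels, CountMatrix

__all__ = ["FeatureRanking", "bw_statistic", "bw_scores", "select_top_genes"]


@dataclass
class FeatureRanking:
    """Per-gene BW scores and the ordered top-p selection."""

    bw_scores: np.ndarray  # length g, aligned to the source gene indexing
    order: np.ndarray      # permutation of gene indices, descending score
    selected: np.ndarray   # first p entries of order
    p: int
    gene_ids: list[str] | None = None

    def __post_init__(self) -> None:
        self.bw_scores = np.asarray(self.bw_scores, dtype=np.float64)
        self.order = np.asarray(self.order, dtype=np.int64)
        self.selected = np.asarray(self.selected, dtype=np.int64)
        g = self.bw_scores.size
        if sorted(self.order.tolist()) != list(range(g)):
            raise ValueError("order is not a permutation of gene indices")
        if self.selected.size != self.p:
            raise ValueError(f"selected has {self.selected.size} entries, p={self.p}")
        ordered = self.bw_scores[self.order]
        if np.any(np.diff(ordered) > 1e-12):
            raise ValueError("scores along order are not non-increasing")


def _expression(matrix: CountMatrix, scale: str) -> np.ndarray:
    if scale == "preprocessed":
        return log_normalize(matrix.counts)
    if scale == "raw":
        return matrix.counts.astype(np.float64)
    raise ValueError(f"unknown scale {scale!r}; expected 'preprocessed' or 'raw'")


def _bw_all(
    values: np.ndarray, labels: np.ndarray, n_classes: int, denominator: str
) -> np.ndarray:
    """Vectorized BW over all genes. values: (g, n); labels: 0-based codes."""
    if n_classes < 2:
        raise ValueError("BW statistic requires at least two classes")
    n_k = np.bincount(labels, minlength=n_classes).astype(np.float64)
    # class means: (K, g)
    sums = np.zeros((n_classes, values.shape[0]))
    for k in range(n_classes):
        sums[k] = values[:, labels == k].sum(axis=1)
    class_means = sums / n_k[:, None]
    grand = class_means.mean(axis=0)  # unweighted mean of class means

    numer = (n_k[:, None] * (class_means - grand[None, :]) ** 2).sum(axis=0)
    if denominator == "grand":
        denom = ((values - grand[:, None]) ** 2).sum(axis=1)
    elif denominator == "within":
        denom = ((values - class_means.T[:, labels]) ** 2).sum(axis=1)
    else:
        raise ValueError(f"unknown denominator {denominator!r}; expected 'grand' or 'within'")
    with np.errstate(invalid="ignore", divide="ignore"):
        bw = np.where(denom > 0, numer / denom, 0.0)
    return bw


def bw_statistic(
    matrix: CountMatrix,
    labels: ClassLabels,
    gene_index: int,
    scale: str = "preprocessed",
    denominator: str = "grand",
) -> float:
    """BW score of a single gene; 0 for a constant gene (zero denominator)."""
    if not 0 <= gene_index < matrix.n_genes:
        raise IndexError(f"gene_index {gene_index} out of range 0..{matrix.n_genes - 1}")
    values = _expression(matrix, scale)[gene_index : gene_index + 1, :]
    return float(_bw_all(values, labels.labels, labels.n_classes, denominator)[0])


def bw_scores(
    matrix: CountMatrix,
    labels: ClassLabels,
    scale: str = "preprocessed",
    denominator: str = "grand",
) -> np.ndarray:
    """BW score for every gene (vectorized)."""
    values = _expression(matrix, scale)
    return _bw_all(values, labels.labels, labels.n_classes, denominator)


def select_top_genes(
    matrix: CountMatrix,
    labels: ClassLabels,
    p: int,
    scale: str = "preprocessed",
    denominator: str = "grand",
) -> FeatureRanking:
    """Rank genes by descending BW on the *training* data and take the top p.

    Ties are broken by ascending gene index (stable sort), so rankings are
    reproducible. The returned ranking must be applied unchanged to test
    data.
    """
    g = matrix.n_genes
    if not 1 <= p <= g:
        raise ValueError(f"p must be in 1..{g}, got {p}")
    scores = bw_scores(matrix, labels, scale=scale, denominator=denominator)
    order = np.argsort(-scores, kind="stable")
    return FeatureRanking(
        bw_scores=scores,
        order=order,
        selected=order[:p],
        p=p,
        gene_ids=list(matrix.gene_ids),
    )
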