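"""Nearest-neighbor cell detection on informative genes.

Follows the scmap projection contract: genes are scored by the residual of
a linear fit of log dropout rate against mean log expression, the
top-scoring genes form the feature space, and cells are ranked by cosine
(or Pearson/Spearman) similarity of their log2(x+1) profiles restricted to
those features. Each query keeps its top ``k`` cells, then drops any whose
similarity falls more than ``gap`` below the best.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata, spearmanr

from .matrix import ExpressionMatrix

__all__ = [
    "FeatureSet",
    "NeighborSet",
    "select_features",
    "cell_similarity",
    "find_neighbors",
    "filter_by_similarity_gap",
]

METRICS = ("cosine", "pearson", "spearman")


@dataclass
class FeatureSet:
    """Selected gene positions with their dropout-residual scores."""

    gene_indices: np.ndarray
    scores: np.ndarray
    fallback: bool = False  # True when variance ranking replaced the residual fit

    def __len__(self) -> int:
        return len(self.gene_indices)


@dataclass
class NeighborSet:
    """Ordered most-similar cells for one query cell."""

    query_cell: str
    query_index: int
    neighbors: list[tuple[str, float]] = field(default_factory=list)
    neighbor_indices: np.ndarray = field(default_factory=lambda: np.empty(0, dtype=int))
    metric: str = "cosine"

    def __len__(self) -> int:
        return len(self.neighbors)

    @property
    def similarities(self) -> np.ndarray:
        return np.array([s for _, s in self.neighbors], dtype=float)


def select_features(m: ExpressionMatrix, n_features: int = 500) -> FeatureSet:
    """Pick genes whose dropout rate is high for their expression level.

    For each gene expressed in some but not all cells, regress
    ``log2(100 * dropout_fraction)`` on the mean of ``log2(x+1)`` by
    ordinary least squares across genes; the score is the residual and the
    ``n_features`` largest-residual genes are returned. Genes with no
    zeros or all zeros carry no dropout signal and are ineligible. If no
    gene is eligible, fall back to the ``n_features`` highest-variance
    genes on the log scale, with a warning.
    """
    X = m.values
    d = np.mean(X == 0, axis=1)
    eligible = (d > 0) & (d < 1)
    logX = np.log2(X + 1.0)
    if not eligible.any():
        warnings.warn(
            "no gene has intermediate dropout; falling back to log-variance ranking",
            UserWarning,
            stacklevel=2,
        )
        var = logX.var(axis=1)
        order = np.lexsort((np.arange(m.n_genes), -var))[:n_features]
        return FeatureSet(gene_indices=np.sort(order), scores=var[np.sort(order)], fallback=True)
    e = logX.mean(axis=1)[eligible]
    y = np.log2(100.0 * d[eligible])
    slope, intercept = np.polyfit(e, y, 1)
    resid = y - (slope * e + intercept)
    idx_eligible = np.flatnonzero(eligible)
    order = np.lexsort((idx_eligible, -resid))[:n_features]
    chosen = idx_eligible[order]
    keep = np.argsort(chosen)  # report features in genomic order
    return FeatureSet(gene_indices=chosen[keep], scores=resid[order][keep])


def _pearson_matrix(F: np.ndarray) -> np.ndarray:
    Fc = F - F.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Fc, axis=1)
    bad = norms == 0
    safe = np.where(bad, 1.0, norms)
    S = (Fc / safe[:, None]) @ (Fc / safe[:, None]).T
    S[bad, :] = 0.0
    S[:, bad] = 0.0
    return S


def _similarity_matrix(F: np.ndarray, metric: str) -> np.ndarray:
    """All-pairs cell similarity for rows of F (cells x features)."""
    if metric == "cosine":
        norms = np.linalg.norm(F, axis=1)
        bad = norms == 0
        if bad.any():
            warnings.warn(f"{bad.sum()} cell(s) have zero norm on the feature space", UserWarning)
        safe = np.where(bad, 1.0, norms)
        S = (F / safe[:, None]) @ (F / safe[:, None]).T
        S[bad, :] = 0.0
        S[:, bad] = 0.0
        return S
    if metric == "pearson":
        return _pearson_matrix(F)
    if metric == "spearman":
        R = np.apply_along_axis(rankdata, 1, F)
        return _pearson_matrix(R)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def cell_similarity(a: np.ndarray, b: np.ndarray, metric: str = "cosine") -> float:
    """Similarity of two cell profiles on the (log-transformed) feature space.

    Degenerate vectors (zero norm for cosine, zero variance for the
    correlations) yield similarity 0 with a warning rather than NaN.
    """
    a = np.asarray(a, dtype=float).ravel()
    b = np.asarray(b, dtype=float).ravel()
    if a.shape != b.shape or a.size < 2:
        raise ValueError("vectors must have equal length >= 2")
    if metric == "cosine":
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            warnings.warn("zero-norm vector in cosine similarity; returning 0", UserWarning)
            return 0.0
        return float(a @ b / (na * nb))
    if metric == "pearson":
        if a.std() == 0 or b.std() == 0:
            warnings.warn("zero-variance vector in Pearson correlation; returning 0", UserWarning)
            return 0.0
        return float(np.corrcoef(a, b)[0, 1])
    if metric == "spearman":
        if a.std() == 0 or b.std() == 0:
            warnings.warn("zero-variance vector in Spearman correlation; returning 0", UserWarning)
            return 0.0
        return float(spearmanr(a, b).statistic)
    raise ValueError(f"unknown metric {metric!r}; choose from {METRICS}")


def find_neighbors(
    m: ExpressionMatrix,
    features: FeatureSet,
    k: int = 20,
    metric: str = "cosine",
    include_self: bool = False,
) -> list[NeighborSet]:
    """Rank, for every cell, the ``k`` most-similar other cells.

    Similarities are computed on log2(x+1) values restricted to the
    selected features; ties are broken by ascending cell index so results
    are deterministic.
    """
    if m.n_cells < 2:
        raise ValueError("neighbor search needs at least two cells")
    F = np.log2(m.values[features.gene_indices, :] + 1.0).T  # cells x features
    S = _similarity_matrix(F, metric)
    n = m.n_cells
    out: list[NeighborSet] = []
    idx = np.arange(n)
    for q in range(n):
        sims = S[q].copy()
        if not include_self:
            sims[q] = -np.inf
        order = np.lexsort((idx, -sims))
        order = order[np.isfinite(sims[order])][:k]
        out.append(
            NeighborSet(
                query_cell=m.cell_names[q],
                query_index=q,
                neighbors=[(m.cell_names[j], float(S[q, j])) for j in order],
                neighbor_indices=order,
                metric=metric,
            )
        )
    return out


def filter_by_similarity_gap(ns: NeighborSet, gap: float = 0.1) -> NeighborSet:
    """Drop neighbors whose similarity is more than ``gap`` below the best.

    The best neighbor always survives, so the result is never empty.
    """
    if len(ns) == 0:
        raise ValueError("empty neighbor set")
    s_max = max(s for _, s in ns.neighbors)
    keep = [i for i, (_, s) in enumerate(ns.neighbors) if s_max - s <= gap]
    return NeighborSet(
        query_cell=ns.query_cell,
        query_index=ns.query_index,
        neighbors=[ns.neighbors[i] for i in keep],
        neighbor_indices=ns.neighbor_indices[keep],
        metric=ns.metric,
    )
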