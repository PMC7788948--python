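"""Outlier-cell removal on nearest-neighbor distances in 2-PC space.

A cell is an outlier when its distance to the closest other cell, computed
on the first two principal components of log1p expression, strictly
exceeds ``q1 + 1.5 * (q3 - q1)`` of the per-cell nearest-distance
distribution. This lower-anchored fence is deliberate (the method defines
it this way); the conventional Tukey fence ``q3 + 1.5 * IQR`` is available
as ``rule="tukey"``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial.distance import squareform, pdist

from .matrix import ExpressionMatrix

__all__ = [
    "OutlierReport",
    "pca_embed",
    "nearest_distances",
    "detect_outliers",
    "filter_outliers",
]


@dataclass
class OutlierReport:
    """Per-cell nearest distances, quartile fence and the resulting split."""

    embedding: np.ndarray
    nearest_distance: np.ndarray
    q1: float
    q3: float
    threshold: float
    outlier_cells: list[str] = field(default_factory=list)
    kept_cells: list[str] = field(default_factory=list)
    rule: str = "q1"

    def to_dict(self) -> dict:
        return {
            "rule": self.rule,
            "q1": self.q1,
            "q3": self.q3,
            "threshold": self.threshold,
            "n_outliers": len(self.outlier_cells),
            "outlier_cells": list(self.outlier_cells),
            "kept_cells": list(self.kept_cells),
            "nearest_distance": [float(d) for d in self.nearest_distance],
        }


def pca_embed(m: ExpressionMatrix, n_components: int = 2) -> np.ndarray:
    """Project cells onto the leading principal components of log1p values.

    Cells are observations (one row per cell); data are centered but not
    scaled. Components are variance-ordered and sign-fixed so the
    largest-magnitude gene loading is positive, making the embedding
    deterministic.
    """
    c = m.n_cells
    if c < max(3, n_components):
        raise ValueError(f"need at least {max(3, n_components)} cells for a {n_components}-PC embedding, got {c}")
    X = np.log1p(m.values.T)  # cells x genes
    Xc = X - X.mean(axis=0)
    U, S, Vt = np.linalg.svd(Xc, full_matrices=False)
    for j in range(n_components):
        i = int(np.argmax(np.abs(Vt[j])))
        if Vt[j, i] < 0:
            Vt[j] *= -1.0
            U[:, j] *= -1.0
    return U[:, :n_components] * S[:n_components]


def nearest_distances(embedding: np.ndarray) -> np.ndarray:
    """Euclidean distance from each cell to its closest other cell."""
    embedding = np.atleast_2d(np.asarray(embedding, dtype=float))
    n = embedding.shape[0]
    if n < 2:
        raise ValueError("nearest distance needs at least two cells")
    D = squareform(pdist(embedding))
    np.fill_diagonal(D, np.inf)
    return D.min(axis=1)


def detect_outliers(dis: np.ndarray, rule: str = "q1") -> tuple[float, float, float, np.ndarray]:
    """Flag cells whose nearest distance strictly exceeds the quartile fence.

    Returns ``(q1, q3, threshold, outlier_indices)``. Quartiles use linear
    interpolation between order statistics.
    """
    dis = np.asarray(dis, dtype=float)
    if dis.size < 4:
        raise ValueError("quartile rule needs at least four cells")
    q1, q3 = np.quantile(dis, [0.25, 0.75])
    iqr = q3 - q1
    if rule == "q1":
        threshold = q1 + 1.5 * iqr
    elif rule == "tukey":
        threshold = q3 + 1.5 * iqr
    else:
        raise ValueError(f"unknown outlier rule {rule!r}")
    return float(q1), float(q3), float(threshold), np.flatnonzero(dis > threshold)


def filter_outliers(
    m: ExpressionMatrix,
    rule: str = "q1",
    n_components: int = 2,
    keep_outliers: bool = False,
) -> tuple[ExpressionMatrix, OutlierReport]:
    """Remove outlier cells before imputation.

    With ``keep_outliers=True`` the returned matrix is the full input and
    outliers are only flagged in the report.
    """
    if m.n_cells < 4:
        raise ValueError(f"outlier filtering needs at least 4 cells, got {m.n_cells}")
    emb = pca_embed(m, n_components=n_components)
    dis = nearest_distances(emb)
    q1, q3, threshold, out_idx = detect_outliers(dis, rule=rule)
    is_out = np.zeros(m.n_cells, dtype=bool)
    is_out[out_idx] = True
    if is_out.all():
        raise ValueError("all cells flagged as outliers; input looks pathological")
    report = OutlierReport(
        embedding=emb,
        nearest_distance=dis,
        q1=q1,
        q3=q3,
        threshold=threshold,
        outlier_cells=[m.cell_names[j] for j in out_idx],
        kept_cells=[m.cell_names[j] for j in np.flatnonzero(~is_out)],
        rule=rule,
    )
    kept = m if keep_outliers else m.subset_cells(~is_out)
    return kept, report
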