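"""Imputation quality metrics: intra/inter-class distances, ARI, zero
accounting, and a PCA scatter.

The compactness score is Dis = Dis_intra / Dis_inter, where Dis_intra is
the sum over classes of the mean squared Euclidean distance between all
ordered within-class cell pairs (self-pairs included, 1/(N_i*N_i)
normalization) and Dis_inter the analogous sum over ordered pairs of
distinct classes. Smaller is better: imputation should pull same-type
cells together more than it pulls different types together.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.spatial.distance import cdist
from sklearn.cluster import KMeans
from sklearn.metrics import adjusted_rand_score

from .matrix import ExpressionMatrix
from .outliers import pca_embed

__all__ = [
    "ClassPartition",
    "DistanceSummary",
    "intra_inter_distance",
    "adjusted_rand_index",
    "cluster_and_score",
    "zero_accounting",
    "pca_scatter",
]


@dataclass
class ClassPartition:
    """Cells grouped by class label."""

    labels: list[str]

    def __post_init__(self) -> None:
        self.labels = [str(x) for x in self.labels]

    @property
    def classes(self) -> list[str]:
        seen: dict[str, None] = {}
        for x in self.labels:
            seen.setdefault(x)
        return list(seen)

    def indices(self, cls: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.labels, dtype=object) == cls)


@dataclass
class DistanceSummary:
    dis_intra: float
    dis_inter: float

    @property
    def dis_ratio(self) -> float:
        if self.dis_inter == 0:
            return float("inf")
        return self.dis_intra / self.dis_inter


def intra_inter_distance(
    m: ExpressionMatrix, part: ClassPartition | list, transform: str = "raw"
) -> DistanceSummary:
    """Class compactness on squared Euclidean distances between cell columns.

    ``transform="raw"`` (default) measures on untransformed values;
    ``"log1p"`` on log(1+x).
    """
    if not isinstance(part, ClassPartition):
        part = ClassPartition(list(part))
    if len(part.labels) != m.n_cells:
        raise ValueError("one label per cell required")
    classes = part.classes
    if len(classes) < 2:
        raise ValueError("inter-class distance needs at least two classes")
    X = m.values.T  # cells x genes
    if transform == "log1p":
        X = np.log1p(X)
    elif transform != "raw":
        raise ValueError(f"unknown transform {transform!r}")
    D2 = cdist(X, X, metric="sqeuclidean")
    groups = {cls: part.indices(cls) for cls in classes}
    intra = 0.0
    for cls in classes:
        idx = groups[cls]
        intra += D2[np.ix_(idx, idx)].sum() / (len(idx) * len(idx))
    inter = 0.0
    for ci in classes:
        for cj in classes:
            if ci == cj:
                continue
            a, b = groups[ci], groups[cj]
            inter += D2[np.ix_(a, b)].sum() / (len(a) * len(b))
    return DistanceSummary(dis_intra=float(intra), dis_inter=float(inter))


def adjusted_rand_index(a, b) -> float:
    """Chance-corrected pair-counting agreement of two labelings in [-1, 1]."""
    a = list(a)
    b = list(b)
    if len(a) != len(b):
        raise ValueError("labelings must have equal length")
    if len(a) < 2:
        raise ValueError("need at least two cells")
    return float(adjusted_rand_score(a, b))


def cluster_and_score(
    m: ExpressionMatrix, true_labels, k: int, seed: int = 0, n_restarts: int = 10
) -> tuple[np.ndarray, float]:
    """K-means on the first two PCs of log(1+x), scored by ARI.

    The log1p + PCA recipe matches the standard visualization transform;
    clustering in that 2-D space keeps raw and imputed matrices on the
    same footing.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    if k > m.n_cells:
        raise ValueError("more clusters than cells")
    true_labels = list(true_labels)
    if len(true_labels) != m.n_cells:
        raise ValueError("one true label per cell required")
    emb = pca_embed(m, n_components=2)
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    pred = km.fit_predict(emb)
    return pred, adjusted_rand_index(true_labels, pred)


def zero_accounting(before: ExpressionMatrix, after: ExpressionMatrix) -> dict:
    """Count how imputation changed the zero pattern.

    ``resolved`` counts entries zero before and nonzero after;
    ``retained_zeros`` entries zero in both. By construction
    ``resolved + retained_zeros == zeros_before``.
    """
    if before.shape != after.shape:
        raise ValueError("matrices must have the same shape")
    if before.gene_names != after.gene_names or before.cell_names != after.cell_names:
        raise ValueError("matrices must carry the same labels")
    zb = before.values == 0
    za = after.values == 0
    total = before.values.size
    return {
        "total_entries": int(total),
        "zeros_before": int(zb.sum()),
        "zeros_after": int(za.sum()),
        "resolved": int((zb & ~za).sum()),
        "retained_zeros": int((zb & za).sum()),
        "zero_fraction_before": float(zb.mean()),
        "zero_fraction_after": float(za.mean()),
    }


def pca_scatter(m: ExpressionMatrix, labels, out, title: str | None = None):
    """Scatter cells on PC1/PC2 of log(1+x), colored by label; save to ``out``."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    labels = [str(x) for x in labels]
    if len(labels) != m.n_cells:
        raise ValueError("one label per cell required")
    emb = pca_embed(m, n_components=2)
    fig, ax = plt.subplots(figsize=(5, 4))
    for cls in dict.fromkeys(labels):
        idx = [j for j, x in enumerate(labels) if x == cls]
        ax.scatter(emb[idx, 0], emb[idx, 1], s=12, label=cls, alpha=0.8)
    ax.set_xlabel("PC1")
    ax.set_ylabel("PC2")
    if title:
        ax.set_title(title)
    ax.legend(frameon=False, fontsize=8)
    fig.tight_layout()
    fig.savefig(out, dpi=150)
    plt.close(fig)
    return out
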