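"""Per-cell dropout imputation driven by the fitted mixtures.

For every query cell, each gene's mixture is fitted on the values of that
gene in the query's neighbor set (read from the original, unmodified
matrix, so cells are independent and the computation is order-free). The
dominant mixture weight then decides: Normal-dominant values are kept,
Binomial-dominant zeros are replaced by the component expectation N*p,
zero-dominant zeros are confirmed as true zeros.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .matrix import ExpressionMatrix
from .mixture import EMConfig, MixtureParams, batch_fit
from .neighbors import NeighborSet, filter_by_similarity_gap, find_neighbors, select_features
from .outliers import OutlierReport, filter_outliers

logger = logging.getLogger(__name__)

__all__ = ["LABELS", "ImputationResult", "decide_and_impute", "impute_cell", "impute_all"]

# provenance codes, stored per entry as uint8
LABELS = ("kept_nonzero", "kept_high", "imputed_dropout", "true_zero", "no_neighbors")
_CODE = {name: i for i, name in enumerate(LABELS)}


@dataclass
class ImputationResult:
    """Modified matrix, per-entry provenance and the run report."""

    matrix: ExpressionMatrix
    provenance: np.ndarray  # uint8 codes into LABELS, genes x kept cells
    report: dict = field(default_factory=dict)
    outlier_report: OutlierReport | None = None

    def label_counts(self) -> dict[str, int]:
        counts = np.bincount(self.provenance.ravel(), minlength=len(LABELS))
        return {name: int(counts[i]) for i, name in enumerate(LABELS)}

    def provenance_labels(self) -> np.ndarray:
        return np.array(LABELS, dtype=object)[self.provenance]


def decide_and_impute(
    x_obs: float, params: MixtureParams, mode: str = "zeros_only"
) -> tuple[float, str]:
    """Apply the dominant-weight decision rule to one observed value.

    Normal-dominant: keep the observation. Binomial-dominant: impute N*p
    (for zeros only in ``zeros_only`` mode; unconditionally in
    ``literal`` mode). Zero-dominant: a zero is confirmed as a true zero;
    a nonzero observation contradicts the zero-dominant model and is kept.
    """
    params.validate()
    if mode not in ("zeros_only", "literal"):
        raise ValueError(f"unknown mode {mode!r}")
    dom = int(np.argmax(params.weights))  # ties -> lowest index
    if dom == 0:
        return float(x_obs), "kept_high"
    if dom == 1:
        if mode == "literal" or x_obs == 0:
            return float(params.N * params.p), "imputed_dropout"
        return float(x_obs), "kept_nonzero"
    if x_obs == 0:
        return 0.0, "true_zero"
    warnings.warn("nonzero observation under a zero-dominant mixture; keeping it", UserWarning)
    return float(x_obs), "kept_nonzero"


def _decide_batch(x_obs: np.ndarray, lam: np.ndarray, N: np.ndarray, p: np.ndarray, mode: str):
    """Vectorized decision rule; returns (values, codes, n_contradictions)."""
    dom = np.argmax(lam, axis=1)
    out = x_obs.astype(float).copy()
    codes = np.empty(x_obs.size, dtype=np.uint8)

    is_zero = x_obs == 0
    m0, m1, m2 = dom == 0, dom == 1, dom == 2
    codes[m0] = _CODE["kept_high"]

    impute_mask = m1 & (is_zero if mode == "zeros_only" else np.ones_like(is_zero))
    out[impute_mask] = (N * p)[impute_mask]
    codes[impute_mask] = _CODE["imputed_dropout"]
    codes[m1 & ~impute_mask] = _CODE["kept_nonzero"]

    true_zero = m2 & is_zero
    out[true_zero] = 0.0
    codes[true_zero] = _CODE["true_zero"]
    contradiction = m2 & ~is_zero
    codes[contradiction] = _CODE["kept_nonzero"]
    return out, codes, int(contradiction.sum())


def impute_cell(
    m: ExpressionMatrix,
    ns: NeighborSet,
    cell: int | str,
    cfg: EMConfig | None = None,
    mode: str = "zeros_only",
) -> tuple[np.ndarray, np.ndarray, dict]:
    """Impute one cell's column; returns (new column, label codes, stats).

    In ``zeros_only`` mode mixtures are fitted only for genes observed at
    zero in the query cell (nonzero entries pass through untouched); in
    ``literal`` mode every gene is fitted. With fewer than two usable
    neighbors the column is returned unchanged and labeled
    ``no_neighbors``.
    """
    cfg = cfg or EMConfig()
    q = m.cell_names.index(cell) if isinstance(cell, str) else int(cell)
    col = m.values[:, q].copy()
    codes = np.full(m.n_genes, _CODE["kept_nonzero"], dtype=np.uint8)
    nbr = ns.neighbor_indices
    if nbr.size < 2:
        logger.warning("cell %s has %d neighbors (<2); column left unchanged", ns.query_cell, nbr.size)
        codes[:] = _CODE["no_neighbors"]
        return col, codes, {"n_neighbors": int(nbr.size), "n_fitted": 0, "contradictions": 0}

    fit_genes = np.flatnonzero(col == 0) if mode == "zeros_only" else np.arange(m.n_genes)
    stats = {"n_neighbors": int(nbr.size), "n_fitted": int(fit_genes.size), "contradictions": 0}
    if fit_genes.size == 0:
        return col, codes, stats
    Z = m.values[np.ix_(fit_genes, nbr)]
    params, n_iter, converged = batch_fit(Z, cfg)
    values, sub_codes, n_contra = _decide_batch(
        col[fit_genes], params.lam, params.N, params.p, mode
    )
    col[fit_genes] = values
    codes[fit_genes] = sub_codes
    stats["contradictions"] = n_contra
    stats["em_iterations"] = n_iter
    stats["em_converged_frac"] = float(converged.mean())
    return col, codes, stats


def impute_all(
    m: ExpressionMatrix,
    cfg: EMConfig | None = None,
    mode: str = "zeros_only",
    n_neighbors: int = 20,
    similarity_gap: float = 0.1,
    n_features: int = 500,
    metric: str = "cosine",
    outlier_rule: str = "q1",
    filter_cells: bool = True,
    keep_outliers: bool = False,
    include_self: bool = False,
) -> ImputationResult:
    """Run the full pipeline: outlier filtering, feature selection,
    neighbor search, then per-cell mixture imputation.

    Every fit reads from the original matrix, so the result does not
    depend on the order in which cells are processed.
    """
    cfg = cfg or EMConfig()
    outlier_report = None
    if filter_cells:
        m, outlier_report = filter_outliers(m, rule=outlier_rule, keep_outliers=keep_outliers)

    features = select_features(m, n_features=n_features)
    neighbor_sets = [
        filter_by_similarity_gap(ns, gap=similarity_gap)
        for ns in find_neighbors(m, features, k=n_neighbors, metric=metric, include_self=include_self)
    ]

    new_values = np.empty_like(m.values)
    provenance = np.empty(m.shape, dtype=np.uint8)
    iter_hist = np.zeros(int(cfg.max_iter) + 1, dtype=int)
    neighbor_counts = []
    contradictions = 0
    for q, ns in enumerate(neighbor_sets):
        col, codes, stats = impute_cell(m, ns, q, cfg=cfg, mode=mode)
        new_values[:, q] = col
        provenance[:, q] = codes
        neighbor_counts.append(stats["n_neighbors"])
        contradictions += stats["contradictions"]
        if "em_iterations" in stats:
            iter_hist += np.bincount(stats["em_iterations"], minlength=iter_hist.size)

    out = ExpressionMatrix(new_values, list(m.gene_names), list(m.cell_names))
    zeros_before = int(np.sum(m.values == 0))
    zeros_after = int(np.sum(new_values == 0))
    result = ImputationResult(matrix=out, provenance=provenance, outlier_report=outlier_report)
    result.report = {
        "mode": mode,
        "n_genes": m.n_genes,
        "n_cells": m.n_cells,
        "n_features": len(features),
        "metric": metric,
        "n_neighbors_requested": n_neighbors,
        "similarity_gap": similarity_gap,
        "neighbor_counts": neighbor_counts,
        "outliers_removed": len(outlier_report.outlier_cells) if outlier_report else 0,
        "label_counts": result.label_counts(),
        "zeros_before": zeros_before,
        "zeros_after": zeros_after,
        "resolved": zeros_before - zeros_after,
        "zero_fraction_before": zeros_before / m.values.size,
        "zero_fraction_after": zeros_after / m.values.size,
        "zero_dominant_contradictions": contradictions,
        "em_iteration_histogram": iter_hist.tolist(),
        "em_config": {
            "max_iter": cfg.max_iter,
            "tol": cfg.tol,
            "sigma_floor": cfg.sigma_floor,
            "p_floor": cfg.p_floor,
        },
    }
    return result
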