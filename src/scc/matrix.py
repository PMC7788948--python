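"""Labeled genes × cells expression matrix container.

The matrix holds raw, untransformed expression values (counts or
count-like numbers): the mixture model downstream is fitted on the
untransformed scale, so no log transform is ever applied here.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = ["ExpressionMatrix"]


@dataclass
class ExpressionMatrix:
    """A genes × cells nonnegative expression matrix with unique labels.

    Parameters
    ----------
    values : ndarray, shape (n_genes, n_cells)
        Nonnegative, finite expression values; raw counts expected.
    gene_names : list of str
        Unique gene identifiers, one per row.
    cell_names : list of str
        Unique cell identifiers, one per column.
    """

    values: np.ndarray
    gene_names: list[str] = field(default_factory=list)
    cell_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("expression matrix must be two-dimensional")
        g, c = self.values.shape
        if g < 1 or c < 1:
            raise ValueError("empty expression matrix (need at least one gene and one cell)")
        if not self.gene_names:
            self.gene_names = [f"gene_{i}" for i in range(g)]
        if not self.cell_names:
            self.cell_names = [f"cell_{j}" for j in range(c)]
        self.gene_names = [str(n) for n in self.gene_names]
        self.cell_names = [str(n) for n in self.cell_names]
        if len(self.gene_names) != g:
            raise ValueError(
                f"gene_names length {len(self.gene_names)} does not match {g} matrix rows"
            )
        if len(self.cell_names) != c:
            raise ValueError(
                f"cell_names length {len(self.cell_names)} does not match {c} matrix columns"
            )
        if len(set(self.gene_names)) != g:
            raise ValueError("duplicate gene names")
        if len(set(self.cell_names)) != c:
            raise ValueError("duplicate cell names")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite expression value")
        if np.any(self.values < 0):
            raise ValueError("negative expression value")

    # -- basic queries -------------------------------------------------
    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_cells(self) -> int:
        return self.values.shape[1]

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    def zero_fraction(self) -> float:
        return float(np.mean(self.values == 0))

    # -- views ---------------------------------------------------------
    def subset_cells(self, idx) -> "ExpressionMatrix":
        """Return a new matrix restricted to cell columns ``idx`` (order kept)."""
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionMatrix(
            self.values[:, idx].copy(),
            list(self.gene_names),
            [self.cell_names[j] for j in idx],
        )

    def subset_genes(self, idx) -> "ExpressionMatrix":
        idx = np.asarray(idx)
        if idx.dtype == bool:
            idx = np.flatnonzero(idx)
        return ExpressionMatrix(
            self.values[idx, :].copy(),
            [self.gene_names[i] for i in idx],
            list(self.cell_names),
        )

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.gene_names, columns=self.cell_names)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame) -> "ExpressionMatrix":
        return cls(df.to_numpy(dtype=float), [str(i) for i in df.index], [str(c) for c in df.columns])

    def check_count_like(self, tol: float = 1e-6, max_noninteger_frac: float = 0.01) -> None:
        """Warn when the data look normalized rather than count-like.

        The Binomial mixture component assumes counts; more than 1% of
        nonzero entries being non-integer triggers a warning, not an error.
        """
        nz = self.values[self.values > 0]
        if nz.size == 0:
            return
        frac = float(np.mean(np.abs(nz - np.rint(nz)) > tol))
        if frac > max_noninteger_frac:
            warnings.warn(
                f"{frac:.1%} of nonzero entries are non-integer; the Binomial "
                "component assumes count-like data",
                UserWarning,
                stacklevel=2,
            )
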