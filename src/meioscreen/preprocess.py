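"""Quality filtering and normalization.

Expression counts are depth-scaled to a fixed size factor (default
10,000) and log1p-transformed; peak counts are TF-IDF weighted
(per-cell term frequency times ``log(1 + n_cells / (1 + n_cells_with_peak))``).
Both keep zeros at zero and are exposed both as sklearn-style
transformers and as the convenience function :func:`normalize`.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import MultiomeDataset, MultiomeError, NormalizedMatrix


def filter_cells_features(ds: MultiomeDataset, min_counts_cell: int = 200,
                          min_cells_feature: int = 3) -> MultiomeDataset:
    """Remove low-depth cells and rarely detected features.

    A cell is dropped when its total count in *either* modality falls
    below ``min_counts_cell`` (it is removed from both matrices, keeping
    them paired).  A gene or peak is dropped when detected (count > 0)
    in fewer than ``min_cells_feature`` of the retained cells.  Ordering
    is otherwise preserved, so the operation is idempotent.
    """
    if min_counts_cell < 0 or min_cells_feature < 0:
        raise MultiomeError("filter thresholds must be >= 0")
    from .datatypes import PeakSet

    expr, peaks_mat = ds.expr, ds.peaks_mat
    cells, genes, peak_table = ds.cells, ds.genes, ds.peak_set.table
    # iterate to a fixpoint: removing features can push a cell below the
    # depth threshold, and vice versa; convergence makes filtering idempotent
    while True:
        expr_depth = np.asarray(expr.sum(axis=1)).ravel()
        peak_depth = np.asarray(peaks_mat.sum(axis=1)).ravel()
        keep_cells = (expr_depth >= min_counts_cell) & (peak_depth >= min_counts_cell)
        if not keep_cells.any():
            raise MultiomeError(
                "all cells removed by min_counts_cell="
                f"{min_counts_cell}; relax the threshold"
            )
        keep_genes = (np.asarray((expr[keep_cells] > 0).sum(axis=0)).ravel()
                      >= min_cells_feature)
        keep_peaks = (np.asarray((peaks_mat[keep_cells] > 0).sum(axis=0)).ravel()
                      >= min_cells_feature)
        if keep_cells.all() and keep_genes.all() and keep_peaks.all():
            break
        expr = expr[keep_cells][:, keep_genes]
        peaks_mat = peaks_mat[keep_cells][:, keep_peaks]
        cells = cells.loc[keep_cells].reset_index(drop=True)
        genes = genes.loc[keep_genes].reset_index(drop=True)
        peak_table = peak_table.loc[keep_peaks].reset_index(drop=True)

    return MultiomeDataset(
        expr=expr, peaks_mat=peaks_mat, cells=cells, genes=genes,
        peak_set=PeakSet(peak_table),
    ).validate()


class LogNormalizer(BaseEstimator, TransformerMixin):
    """Depth-scale each cell to ``size_factor`` total counts, then log1p.

    Stateless apart from recording the size factor; ``fit`` validates
    that every cell has positive depth.
    """

    def __init__(self, size_factor: float = 1e4):
        self.size_factor = size_factor

    def fit(self, X, y=None):
        X = sp.csr_matrix(X)
        depth = np.asarray(X.sum(axis=1)).ravel()
        if (depth <= 0).any():
            raise MultiomeError(
                "cell(s) with zero total counts under expression "
                "normalization; filter cells first"
            )
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> sp.csr_matrix:
        X = sp.csr_matrix(X, dtype=float)
        depth = np.asarray(X.sum(axis=1)).ravel()
        if (depth <= 0).any():
            raise MultiomeError(
                "cell(s) with zero total counts under expression "
                "normalization; filter cells first"
            )
        out = X.copy()
        scale = self.size_factor / depth
        out.data = out.data * np.repeat(scale, np.diff(out.indptr))
        out.data = np.log1p(out.data)
        return out


class TfidfNormalizer(BaseEstimator, TransformerMixin):
    """TF-IDF weighting for the peak matrix.

    Term frequency is count over cell total, scaled to ``size_factor``
    (counts per 10,000 by default, so values are O(1) and comparable to
    log-normalized expression); inverse document frequency is
    ``log(1 + n_cells / (1 + n_cells_with_peak))``, learned in ``fit``
    and stored as ``idf_``.
    """

    def __init__(self, size_factor: float = 1e4):
        self.size_factor = size_factor

    def fit(self, X, y=None):
        X = sp.csr_matrix(X)
        n_cells = X.shape[0]
        df = np.asarray((X > 0).sum(axis=0)).ravel()
        self.idf_ = np.log(1.0 + n_cells / (1.0 + df))
        self.n_features_in_ = X.shape[1]
        return self

    def transform(self, X) -> sp.csr_matrix:
        if not hasattr(self, "idf_"):
            raise MultiomeError("TfidfNormalizer must be fit before transform")
        X = sp.csr_matrix(X, dtype=float)
        depth = np.asarray(X.sum(axis=1)).ravel()
        scale = np.divide(self.size_factor, depth,
                          out=np.zeros_like(depth, dtype=float),
                          where=depth > 0)
        out = X.copy()
        out.data = out.data * np.repeat(scale, np.diff(out.indptr))
        out = out.multiply(self.idf_[None, :]).tocsr()
        return out


def normalize(matrix, kind: str, size_factor: float = 1e4) -> NormalizedMatrix:
    """Normalize a count matrix; ``kind`` is ``"expression"`` or ``"peaks"``."""
    if kind == "expression":
        t = LogNormalizer(size_factor=size_factor).fit(matrix)
        return NormalizedMatrix(values=t.transform(matrix), method="expression",
                                params={"size_factor": size_factor})
    if kind == "peaks":
        t = TfidfNormalizer(size_factor=size_factor).fit(matrix)
        return NormalizedMatrix(
            values=t.transform(matrix), method="peaks",
            params={"size_factor": size_factor,
                    "idf": "log(1 + n_cells / (1 + n_cells_with_peak))"},
        )
    raise MultiomeError(f"unknown normalization kind {kind!r}")
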