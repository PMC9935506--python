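"""Gene activity scores from chromatin accessibility.

For each gene, accessibility counts are summed over the peaks that
overlap the gene body extended ``upstream_bp`` upstream of the TSS
(``[start - upstream_bp, end)`` on the + strand, ``[start, end +
upstream_bp)`` on the - strand), then depth-normalized like expression
using each cell's total fragment count.
"""

from __future__ import annotations

import numpy as np
import scipy.sparse as sp
from intervaltree import IntervalTree

from .datatypes import GeneAnnotation, MultiomeError, PeakSet


def gene_activity_scores(peaks_mat, peak_set: PeakSet, genes: GeneAnnotation,
                         upstream_bp: int = 2000,
                         size_factor: float = 1e4) -> np.ndarray:
    """Cells x genes activity matrix (log1p of depth-scaled summed counts)."""
    if upstream_bp < 0:
        raise MultiomeError("upstream_bp must be >= 0")
    peaks_mat = sp.csr_matrix(peaks_mat, dtype=float)
    if peaks_mat.shape[1] != len(peak_set):
        raise MultiomeError("peak matrix width does not match peak set")

    trees: dict[str, IntervalTree] = {}
    for i, r in enumerate(peak_set.table.itertuples(index=False)):
        trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, i)

    n_genes = len(genes)
    cols, rows = [], []
    for g, rec in enumerate(genes.table.itertuples(index=False)):
        if rec.strand == "+":
            lo, hi = max(0, rec.start - upstream_bp), rec.end
        else:
            lo, hi = rec.start, rec.end + upstream_bp
        if hi <= lo:
            continue
        for iv in trees.get(rec.chrom, IntervalTree()).overlap(lo, hi):
            rows.append(iv.data)
            cols.append(g)
    indicator = sp.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(len(peak_set), n_genes))
    raw = np.asarray((peaks_mat @ indicator).todense())

    depth = np.asarray(peaks_mat.sum(axis=1)).ravel()
    scale = np.divide(size_factor, depth, out=np.zeros_like(depth),
                      where=depth > 0)
    return np.log1p(raw * scale[:, None])
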