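"""Shared data containers for the multiome screening pipeline.

The pipeline operates on a paired single-cell dataset: a cells x genes
transcript count matrix and a cells x peaks chromatin-accessibility count
matrix over the same ordered set of cells, each cell labelled with one of
the five germ-cell stages spanning the mitotic/meiotic switch
(mitotic, transition, preleptotene, leptotene, zygotene).

Containers are thin dataclasses around pandas tables and scipy sparse
matrices; ``validate()`` enforces the structural invariants every stage
of the pipeline relies on (paired cell ordering, closed stage vocabulary,
unique identifiers, well-formed intervals).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
import scipy.sparse as sp

#: Closed vocabulary of germ-cell stages, in developmental order.
STAGES = ("mitotic", "transition", "preleptotene", "leptotene", "zygotene")

#: Default pre-meiotic stage set (before meiotic initiation at preleptotene).
PRE_MEIOTIC_STAGES = ("mitotic", "transition")


class MultiomeError(ValueError):
    """Structured error for malformed multiome inputs."""


def _as_csr(m) -> sp.csr_matrix:
    if sp.issparse(m):
        return m.tocsr()
    return sp.csr_matrix(np.asarray(m))


@dataclass
class PeakSet:
    """Ordered set of accessible-chromatin intervals (BED-style 0-based half-open)."""

    table: pd.DataFrame  # columns: peak_id, chrom, start, end

    def __post_init__(self) -> None:
        required = ["peak_id", "chrom", "start", "end"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise MultiomeError(f"PeakSet table missing columns {missing}")
        self.table = self.table.reset_index(drop=True)

    def validate(self) -> "PeakSet":
        t = self.table
        if t["peak_id"].duplicated().any():
            dup = t.loc[t["peak_id"].duplicated(), "peak_id"].iloc[0]
            raise MultiomeError(f"duplicate peak_id {dup!r}")
        bad = t.index[(t["start"] >= t["end"]) | (t["start"] < 0)]
        if len(bad):
            i = int(bad[0])
            raise MultiomeError(
                f"malformed interval at peak row {i}: "
                f"{t.loc[i, 'chrom']}:{t.loc[i, 'start']}-{t.loc[i, 'end']} "
                "(require 0 <= start < end)"
            )
        return self

    @property
    def peak_ids(self) -> np.ndarray:
        return self.table["peak_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class GeneAnnotation:
    """Gene coordinates with strand and the derived TSS position.

    TSS equals ``start`` on the + strand and ``end`` on the - strand
    (coordinates 0-based half-open like the peak intervals).
    """

    table: pd.DataFrame  # columns: gene_id, chrom, strand, start, end

    def __post_init__(self) -> None:
        required = ["gene_id", "chrom", "strand", "start", "end"]
        missing = [c for c in required if c not in self.table.columns]
        if missing:
            raise MultiomeError(f"GeneAnnotation table missing columns {missing}")
        self.table = self.table.reset_index(drop=True)
        if "tss" not in self.table.columns:
            self.table["tss"] = np.where(
                self.table["strand"] == "+", self.table["start"], self.table["end"]
            )

    def validate(self) -> "GeneAnnotation":
        t = self.table
        if t["gene_id"].duplicated().any():
            dup = t.loc[t["gene_id"].duplicated(), "gene_id"].iloc[0]
            raise MultiomeError(f"duplicate gene_id {dup!r}")
        if not t["strand"].isin(["+", "-"]).all():
            raise MultiomeError("strand must be '+' or '-' for every gene")
        if (t["start"] > t["end"]).any() or (t["start"] < 0).any():
            raise MultiomeError("gene coordinates must satisfy 0 <= start <= end")
        expected_tss = np.where(t["strand"] == "+", t["start"], t["end"])
        if not np.array_equal(t["tss"].to_numpy(), expected_tss):
            raise MultiomeError("tss must equal start (+) or end (-) for every gene")
        return self

    @property
    def gene_ids(self) -> np.ndarray:
        return self.table["gene_id"].to_numpy()

    def __len__(self) -> int:
        return len(self.table)


@dataclass
class MultiomeDataset:
    """Paired scRNA + scATAC count matrices over one ordered cell set."""

    expr: sp.csr_matrix          # cells x genes, non-negative integer counts
    peaks_mat: sp.csr_matrix     # cells x peaks, non-negative integer counts
    cells: pd.DataFrame          # columns: cell_id, stage[, embryonic_day]
    genes: pd.DataFrame          # columns: gene_id (at minimum)
    peak_set: PeakSet

    def __post_init__(self) -> None:
        self.expr = _as_csr(self.expr)
        self.peaks_mat = _as_csr(self.peaks_mat)
        self.cells = self.cells.reset_index(drop=True)
        self.genes = self.genes.reset_index(drop=True)

    def validate(self) -> "MultiomeDataset":
        n_cells = len(self.cells)
        if self.expr.shape[0] != n_cells:
            raise MultiomeError(
                f"expression matrix has {self.expr.shape[0]} cells but the "
                f"cell table has {n_cells} rows"
            )
        if self.peaks_mat.shape[0] != n_cells:
            raise MultiomeError(
                f"peak matrix has {self.peaks_mat.shape[0]} cells but the "
                f"cell table has {n_cells} rows"
            )
        if self.expr.shape[1] != len(self.genes):
            raise MultiomeError(
                f"expression matrix has {self.expr.shape[1]} genes but the "
                f"gene table has {len(self.genes)} rows"
            )
        if self.peaks_mat.shape[1] != len(self.peak_set):
            raise MultiomeError(
                f"peak matrix has {self.peaks_mat.shape[1]} peaks but the "
                f"peak set has {len(self.peak_set)} intervals"
            )
        unknown = set(self.cells["stage"]) - set(STAGES)
        if unknown:
            raise MultiomeError(
                f"unknown stage label(s) {sorted(unknown)}; allowed stages are "
                f"{list(STAGES)}"
            )
        if self.cells["cell_id"].duplicated().any():
            raise MultiomeError("duplicate cell_id in cell table")
        if self.genes["gene_id"].duplicated().any():
            raise MultiomeError("duplicate gene_id in gene table")
        self.peak_set.validate()
        if self.expr.nnz and self.expr.data.min() < 0:
            raise MultiomeError("negative entries in expression matrix")
        if self.peaks_mat.nnz and self.peaks_mat.data.min() < 0:
            raise MultiomeError("negative entries in peak matrix")
        return self

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def stage_mask(self, stage: str) -> np.ndarray:
        if stage not in STAGES:
            raise MultiomeError(f"unknown stage {stage!r}; allowed: {list(STAGES)}")
        mask = (self.cells["stage"] == stage).to_numpy()
        if not mask.any():
            present = sorted(self.cells["stage"].unique())
            raise MultiomeError(f"stage {stage!r} absent; available stages: {present}")
        return mask


@dataclass
class NormalizedMatrix:
    """A normalized cells x features matrix with its provenance.

    ``method`` is ``"expression"`` (depth scaling to a fixed size factor,
    then log1p) or ``"peaks"`` (per-cell term frequency x log inverse
    document frequency).  ``params`` records the scale parameters used.
    """

    values: sp.csr_matrix
    method: str
    params: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = _as_csr(self.values)
        if not np.isfinite(self.values.data).all():
            raise MultiomeError("normalized matrix contains non-finite values")

    def toarray(self) -> np.ndarray:
        return self.values.toarray()


@dataclass
class MotifHitMatrix:
    """Peaks x motifs incidence with a best-match log-odds score per hit.

    ``scores`` is sparse and parallel to ``hits``: a score is present
    iff the corresponding hit is present.
    """

    hits: sp.csr_matrix          # peaks x motifs, 0/1
    scores: sp.csr_matrix        # peaks x motifs, log-odds of best match where hit
    peak_ids: np.ndarray
    motif_ids: np.ndarray

    def __post_init__(self) -> None:
        self.hits = _as_csr(self.hits)
        self.scores = _as_csr(self.scores)
        self.peak_ids = np.asarray(self.peak_ids)
        self.motif_ids = np.asarray(self.motif_ids)
        if self.hits.shape != self.scores.shape:
            raise MultiomeError("hits and scores must have identical shape")
        if self.hits.shape != (len(self.peak_ids), len(self.motif_ids)):
            raise MultiomeError(
                f"hit matrix shape {self.hits.shape} does not match "
                f"{len(self.peak_ids)} peaks x {len(self.motif_ids)} motifs"
            )

    def motif_index(self, motif_id: str) -> int:
        idx = np.flatnonzero(self.motif_ids == motif_id)
        if len(idx) == 0:
            raise MultiomeError(f"motif {motif_id!r} absent from hit matrix")
        return int(idx[0])

    def peaks_with_motif(self, motif_id: str) -> np.ndarray:
        """Row indices of peaks carrying the motif."""
        j = self.motif_index(motif_id)
        return self.hits[:, j].tocoo().row


@dataclass
class DeviationMatrix:
    """Cells x motifs accessibility-deviation z-scores with provenance."""

    z: np.ndarray                # cells x motifs
    raw: np.ndarray              # cells x motifs raw deviations
    motif_ids: np.ndarray
    n_background: int
    seed: int
    missing: np.ndarray = None   # bool per motif: deviation undefined (no hit peaks)

    def __post_init__(self) -> None:
        self.motif_ids = np.asarray(self.motif_ids)
        if self.missing is None:
            self.missing = np.zeros(len(self.motif_ids), dtype=bool)

    def frame(self, cell_ids=None) -> pd.DataFrame:
        return pd.DataFrame(self.z, columns=self.motif_ids, index=cell_ids)
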