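"""Readers and writers for the plain-text exchange formats.

Matrices travel as matrix-market triplets (.mtx) with TSV sidecars for
cell and gene metadata, peaks as BED3+name, gene annotation as a
five-column TSV, motif models as JASPAR-style position frequency
matrices, and motif hits as a three-column TSV.  All writers are
deterministic given fixed inputs.
"""

from __future__ import annotations

import os
import warnings
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import scipy.io as sio
import scipy.sparse as sp

from .datatypes import (
    GeneAnnotation,
    MotifHitMatrix,
    MultiomeDataset,
    MultiomeError,
    PeakSet,
    STAGES,
)


# ---------------------------------------------------------------------------
# BED / annotation
# ---------------------------------------------------------------------------

def read_bed(path) -> PeakSet:
    """Read peaks from BED3+name (chrom, start, end, peak_id).

    Raises :class:`MultiomeError` naming the offending line for malformed
    intervals.
    """
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t") if "\t" in line else line.split()
            if len(parts) < 3:
                raise MultiomeError(f"{path}: BED line {lineno}: fewer than 3 fields")
            chrom = parts[0]
            try:
                start, end = int(parts[1]), int(parts[2])
            except ValueError as exc:
                raise MultiomeError(
                    f"{path}: BED line {lineno}: non-integer coordinates"
                ) from exc
            if start < 0 or start >= end:
                raise MultiomeError(
                    f"{path}: BED line {lineno}: malformed interval "
                    f"{chrom}:{start}-{end} (require 0 <= start < end)"
                )
            name = parts[3] if len(parts) > 3 else f"peak_{lineno}"
            rows.append((name, chrom, start, end))
    return PeakSet(
        pd.DataFrame(rows, columns=["peak_id", "chrom", "start", "end"])
    ).validate()


def write_bed(peaks: PeakSet, path) -> None:
    t = peaks.table
    with open(path, "w") as fh:
        for _, r in t.iterrows():
            fh.write(f"{r['chrom']}\t{r['start']}\t{r['end']}\t{r['peak_id']}\n")


def read_gene_annotation(path) -> GeneAnnotation:
    """Read gene annotation TSV (gene_id, chrom, strand, start, end)."""
    t = pd.read_csv(path, sep="\t", dtype={"gene_id": str, "chrom": str, "strand": str})
    return GeneAnnotation(t).validate()


def write_gene_annotation(genes: GeneAnnotation, path) -> None:
    genes.table[["gene_id", "chrom", "strand", "start", "end"]].to_csv(
        path, sep="\t", index=False
    )


# ---------------------------------------------------------------------------
# Multiome bundle
# ---------------------------------------------------------------------------

def load_multiome(expr_path, peaks_path, cells_path, genes_path, bed_path) -> MultiomeDataset:
    """Load a paired multiome dataset from its on-disk parts.

    Matrices are matrix-market triplets oriented cells x features; the
    cell order of the returned dataset is the row order of the cells TSV.
    """
    expr = sp.csr_matrix(sio.mmread(expr_path))
    peaks_mat = sp.csr_matrix(sio.mmread(peaks_path))
    cells = pd.read_csv(cells_path, sep="\t", dtype={"cell_id": str, "stage": str})
    genes = pd.read_csv(genes_path, sep="\t", dtype={"gene_id": str})
    peak_set = read_bed(bed_path)

    if expr.shape[0] != len(cells):
        raise MultiomeError(
            f"{expr_path}: matrix has {expr.shape[0]} rows (cells) but "
            f"{cells_path} has {len(cells)} rows"
        )
    if peaks_mat.shape[0] != len(cells):
        raise MultiomeError(
            f"{peaks_path}: matrix has {peaks_mat.shape[0]} rows (cells) but "
            f"{cells_path} has {len(cells)} rows"
        )
    if expr.shape[1] != len(genes):
        raise MultiomeError(
            f"{expr_path}: matrix has {expr.shape[1]} columns (genes) but "
            f"{genes_path} has {len(genes)} rows"
        )
    if peaks_mat.shape[1] != len(peak_set):
        raise MultiomeError(
            f"{peaks_path}: matrix has {peaks_mat.shape[1]} columns (peaks) but "
            f"{bed_path} has {len(peak_set)} intervals"
        )
    ds = MultiomeDataset(expr=expr, peaks_mat=peaks_mat, cells=cells,
                         genes=genes, peak_set=peak_set)
    return ds.validate()


def write_multiome(ds: MultiomeDataset, outdir) -> dict:
    """Write a dataset to ``outdir``; returns the path map used."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "expr": outdir / "expr.mtx",
        "peaks": outdir / "peaks.mtx",
        "cells": outdir / "cells.tsv",
        "genes": outdir / "genes.tsv",
        "bed": outdir / "peaks.bed",
    }
    sio.mmwrite(str(paths["expr"]), sp.coo_matrix(ds.expr))
    sio.mmwrite(str(paths["peaks"]), sp.coo_matrix(ds.peaks_mat))
    ds.cells.to_csv(paths["cells"], sep="\t", index=False)
    ds.genes.to_csv(paths["genes"], sep="\t", index=False)
    write_bed(ds.peak_set, paths["bed"])
    return {k: str(v) for k, v in paths.items()}


# ---------------------------------------------------------------------------
# Motifs
# ---------------------------------------------------------------------------

def read_jaspar_pfms(path):
    """Parse JASPAR-style plain-text PFMs into MotifModel objects.

    Accepts both the bracketed ``A [ 1 2 3 ]`` row format and bare
    4-row count blocks under each ``>motif_id name`` header.
    """
    from .motifs import MotifModel

    models = []
    header = None
    rows: list[list[float]] = []

    def flush():
        nonlocal header, rows
        if header is None:
            return
        if len(rows) != 4:
            raise MultiomeError(
                f"motif {header[0]!r}: expected 4 base rows, found {len(rows)}"
            )
        counts = np.array(rows, dtype=float).T  # L x 4 (A,C,G,T)
        denom = counts.sum(axis=1, keepdims=True)
        if (denom <= 0).any():
            raise MultiomeError(f"motif {header[0]!r}: zero-count column")
        models.append(MotifModel(motif_id=header[0], tf_name=header[1],
                                 pwm=counts / denom))
        header, rows = None, []

    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith(">"):
                flush()
                parts = line[1:].split(None, 1)
                header = (parts[0], parts[1].strip() if len(parts) > 1 else parts[0])
            else:
                cleaned = line
                for ch in "ACGTacgt[]":
                    cleaned = cleaned.replace(ch, " ")
                vals = [float(x) for x in cleaned.split()]
                if vals:
                    rows.append(vals)
    flush()
    return models


def read_motif_hits(path, peak_ids: Sequence[str], motif_ids: Sequence[str]) -> MotifHitMatrix:
    """Read a precomputed hit table TSV (peak_id, motif_id, score)."""
    t = pd.read_csv(path, sep="\t", dtype={"peak_id": str, "motif_id": str})
    peak_ids = np.asarray(peak_ids)
    motif_ids = np.asarray(motif_ids)
    p_index = {p: i for i, p in enumerate(peak_ids)}
    m_index = {m: j for j, m in enumerate(motif_ids)}
    unknown_m = set(t["motif_id"]) - set(m_index)
    if unknown_m:
        raise MultiomeError(f"hit table references unknown motifs {sorted(unknown_m)[:5]}")
    unknown_p = set(t["peak_id"]) - set(p_index)
    if unknown_p:
        raise MultiomeError(f"hit table references unknown peaks {sorted(unknown_p)[:5]}")
    rows = t["peak_id"].map(p_index).to_numpy()
    cols = t["motif_id"].map(m_index).to_numpy()
    shape = (len(peak_ids), len(motif_ids))
    hits = sp.csr_matrix((np.ones(len(t)), (rows, cols)), shape=shape)
    hits.data[:] = 1.0  # collapse duplicates
    scores = sp.csr_matrix((t["score"].to_numpy(float), (rows, cols)), shape=shape)
    return MotifHitMatrix(hits=hits, scores=scores, peak_ids=peak_ids, motif_ids=motif_ids)


def write_motif_hits(hits: MotifHitMatrix, path) -> None:
    coo = hits.hits.tocoo()
    scores = hits.scores.toarray()
    order = np.lexsort((coo.col, coo.row))
    with open(path, "w") as fh:
        fh.write("peak_id\tmotif_id\tscore\n")
        for k in order:
            i, j = coo.row[k], coo.col[k]
            fh.write(f"{hits.peak_ids[i]}\t{hits.motif_ids[j]}\t{scores[i, j]:.6g}\n")


def read_tf_map(path) -> pd.DataFrame:
    """Motif->gene map TSV with columns motif_id, tf_name, gene_id."""
    t = pd.read_csv(path, sep="\t", dtype=str)
    required = {"motif_id", "tf_name", "gene_id"}
    if not required.issubset(t.columns):
        raise MultiomeError(f"tf map must have columns {sorted(required)}")
    return t
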