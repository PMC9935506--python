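"""TF-TF interaction scoring, promoter target annotation, amplification.

The interaction score between two TFs follows the multiplicative rule

    score(TF1 -> TF2, stage) = E x M x P

with E the stage-mean expression of TF1's gene, M the stage-mean motif
score of TF1 (by default the motif-activity deviation shifted to be
non-negative across stages), and P the stage-mean accessibility (Tn5
score, TF-IDF normalized) of TF2's promoter peaks that carry TF1's
motif.  A TF1 -> TF2 edge requires a TF1 motif inside a peak within
the TF2 promoter window (TSS +/- 3 kb by default); with no qualifying
peak, P = 0 and the edge score is 0.

The amplification statistic asks what fraction of leptotene-upregulated
genes were already expressed before meiotic initiation (mitotic and
transition stages): genes whose pre-meiotic mean expression clears a
threshold — by default 10% of their own leptotene mean — count as
pre-expressed (amplified rather than switched on).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from intervaltree import IntervalTree

from .datatypes import (
    GeneAnnotation,
    MotifHitMatrix,
    MultiomeError,
    PeakSet,
    PRE_MEIOTIC_STAGES,
)

DEFAULT_PROMOTER_WINDOW = 3000  # bp each side of the TSS


def promoter_peak_map(peaks: PeakSet, genes: GeneAnnotation,
                      w: int = DEFAULT_PROMOTER_WINDOW) -> dict[str, list[str]]:
    """Map each gene to the peaks overlapping its promoter window.

    The window is the half-open interval ``[tss - w, tss + w)``; overlap
    is half-open interval intersection.  Peaks on chromosomes absent
    from the gene annotation are skipped with a warning.
    """
    if w < 0:
        raise MultiomeError("promoter window must be >= 0")
    gene_chroms = set(genes.table["chrom"])
    trees: dict[str, IntervalTree] = {}
    skipped = 0
    for _, r in peaks.table.iterrows():
        if r["chrom"] not in gene_chroms:
            skipped += 1
            continue
        trees.setdefault(r["chrom"], IntervalTree()).addi(
            r["start"], r["end"], r["peak_id"])
    if skipped:
        warnings.warn(f"{skipped} peak(s) on chromosomes absent from the gene "
                      "annotation were skipped", stacklevel=2)
    out: dict[str, list[str]] = {}
    for _, g in genes.table.iterrows():
        lo = max(0, int(g["tss"]) - w)
        hi = int(g["tss"]) + w
        if hi <= lo:
            # w == 0: the window is the single TSS base
            hi = lo + 1 if w == 0 else hi
        found = trees.get(g["chrom"], IntervalTree()).overlap(lo, hi) if hi > lo else set()
        out[g["gene_id"]] = sorted(iv.data for iv in found)
    return out


def stage_means(matrix, cells, stage: str) -> np.ndarray:
    """Arithmetic per-feature mean over the cells of one stage."""
    stages = pd.Series(cells["stage"]) if hasattr(cells, "columns") else pd.Series(cells)
    mask = (stages == stage).to_numpy()
    if not mask.any():
        present = sorted(stages.unique())
        raise MultiomeError(f"stage {stage!r} absent; available stages: {present}")
    if sp.issparse(matrix):
        return np.asarray(matrix[mask].mean(axis=0)).ravel()
    return np.asarray(matrix)[mask].mean(axis=0)


@dataclass
class InteractionEdge:
    """A scored TF1 -> TF2 edge with its three components."""

    tf_from: str
    tf_to: str
    stage: str
    expression: float       # E: mean expression of tf_from's gene
    motif_score: float      # M: mean motif score of tf_from
    promoter_tn5: float     # P: mean accessibility of qualifying promoter peaks
    score: float
    n_qualifying_peaks: int
    self_edge: bool = False
    strength: str = ""


@dataclass
class TFContext:
    """Indexes shared by the interaction-score operations."""

    hits: MotifHitMatrix
    pmap: dict[str, list[str]]
    tf_map: pd.DataFrame          # motif_id, tf_name, gene_id
    gene_ids: np.ndarray
    peak_ids: np.ndarray
    gene_index: dict = field(init=False)
    peak_index: dict = field(init=False)
    by_tf: dict = field(init=False)

    def __post_init__(self) -> None:
        self.gene_index = {g: i for i, g in enumerate(self.gene_ids)}
        self.peak_index = {p: i for i, p in enumerate(self.peak_ids)}
        self.by_tf = {r["tf_name"]: (r["motif_id"], r["gene_id"])
                      for _, r in self.tf_map.iterrows()}

    def lookup(self, tf: str) -> tuple[str, str]:
        if tf not in self.by_tf:
            raise MultiomeError(f"unknown TF {tf!r}")
        return self.by_tf[tf]


def nonnegative_motif_scores(dev_stage_means: pd.DataFrame) -> pd.DataFrame:
    """Shift per-motif stage-mean deviations to be non-negative.

    ``dev_stage_means`` is stages x motifs; each motif column is shifted
    by its minimum across stages (then floored at 0) so the
    multiplicative interaction score stays sign-stable.
    """
    shifted = dev_stage_means - dev_stage_means.min(axis=0)
    return shifted.clip(lower=0.0)


def interaction_score(tf_from: str, tf_to: str, stage: str,
                      expr_means: pd.Series, motif_means: pd.Series,
                      peak_means: pd.Series, ctx: TFContext) -> InteractionEdge:
    """Score one ordered TF pair at one stage (score = E x M x P).

    ``expr_means`` (per gene), ``motif_means`` (per motif) and
    ``peak_means`` (per peak) are stage-mean vectors for ``stage``.
    """
    motif_from, gene_from = ctx.lookup(tf_from)
    _, gene_to = ctx.lookup(tf_to)
    if gene_to not in ctx.pmap:
        raise MultiomeError(f"gene {gene_to!r} missing from promoter map")
    promoter_peaks = ctx.pmap[gene_to]
    j = ctx.hits.motif_index(motif_from)
    hit_rows = set(ctx.hits.hits[:, j].tocoo().row)
    qualifying = [p for p in promoter_peaks
                  if ctx.peak_index.get(p) in hit_rows]
    E = float(expr_means[gene_from])
    M = float(motif_means[motif_from])
    if qualifying:
        P = float(np.mean([peak_means[p] for p in qualifying]))
    else:
        P = 0.0
    return InteractionEdge(
        tf_from=tf_from, tf_to=tf_to, stage=stage,
        expression=E, motif_score=M, promoter_tn5=P,
        score=E * M * P, n_qualifying_peaks=len(qualifying),
        self_edge=tf_from == tf_to,
    )


def build_interaction_network(core_tfs, stage: str, expr_means: pd.Series,
                              motif_means: pd.Series, peak_means: pd.Series,
                              ctx: TFContext,
                              strong_quantile: float = 0.75) -> pd.DataFrame:
    """Score all ordered core-TF pairs at one stage.

    Edges at or above the ``strong_quantile`` quantile of nonzero,
    non-self scores are labelled ``strong``, the rest ``weak``.
    Self-edges are computed but flagged.
    """
    core_tfs = list(core_tfs)
    if len(core_tfs) < 2:
        raise MultiomeError("need at least 2 core TFs to build a network")
    edges = []
    for tf1 in core_tfs:
        for tf2 in core_tfs:
            edges.append(interaction_score(tf1, tf2, stage, expr_means,
                                           motif_means, peak_means, ctx))
    scores = np.array([e.score for e in edges])
    nonself = np.array([not e.self_edge for e in edges])
    nonzero = scores[nonself & (scores > 0)]
    cutoff = np.quantile(nonzero, strong_quantile) if nonzero.size else np.inf
    for e in edges:
        e.strength = "strong" if (e.score >= cutoff and e.score > 0) else "weak"
    table = pd.DataFrame([{
        "tf_from": e.tf_from, "tf_to": e.tf_to, "stage": e.stage,
        "expression": e.expression, "motif_score": e.motif_score,
        "promoter_tn5": e.promoter_tn5, "score": e.score,
        "n_qualifying_peaks": e.n_qualifying_peaks,
        "self_edge": e.self_edge, "strength": e.strength,
    } for e in edges])
    return table.sort_values("score", ascending=False).reset_index(drop=True)


def tf_target_genes(tf: str, hits: MotifHitMatrix,
                    pmap: dict[str, list[str]], ctx: TFContext = None,
                    motif_id: str = None) -> pd.DataFrame:
    """Genes with >= 1 promoter peak carrying the TF's motif.

    Returns a table (gene_id, peak_id, motif_score) with one row per
    supporting peak.
    """
    if motif_id is None:
        if ctx is None:
            raise MultiomeError("provide either ctx or motif_id")
        motif_id, _ = ctx.lookup(tf)
    j = hits.motif_index(motif_id)
    hit_rows = set(hits.hits[:, j].tocoo().row)
    peak_index = {p: i for i, p in enumerate(hits.peak_ids)}
    scores = hits.scores
    rows = []
    for gene, promoter_peaks in pmap.items():
        for p in promoter_peaks:
            i = peak_index.get(p)
            if i in hit_rows:
                rows.append({"tf_name": tf, "gene_id": gene, "peak_id": p,
                             "motif_score": float(scores[i, j])})
    return (pd.DataFrame(rows, columns=["tf_name", "gene_id", "peak_id", "motif_score"])
            .sort_values(["gene_id", "peak_id"]).reset_index(drop=True))


@dataclass
class AmplificationResult:
    n_up: int
    n_pre: int
    fraction: float
    threshold_mode: str
    expr_threshold: float
    pre_stages: tuple


def amplification_fraction(expr_norm, cells, up_genes, gene_ids,
                           pre_stages=PRE_MEIOTIC_STAGES,
                           expr_threshold: float = 0.1,
                           threshold_mode: str = "relative",
                           ref_stage: str = "leptotene") -> AmplificationResult:
    """Fraction of upregulated genes already expressed pre-meiotically.

    ``threshold_mode="relative"`` counts a gene as pre-expressed when its
    mean normalized expression over ``pre_stages`` is at least
    ``expr_threshold`` times its own ``ref_stage`` mean;
    ``"absolute"`` compares the pre-meiotic mean to ``expr_threshold``
    directly.
    """
    up_genes = list(up_genes)
    if not up_genes:
        raise MultiomeError("up_genes must be non-empty")
    if threshold_mode not in ("relative", "absolute"):
        raise MultiomeError("threshold_mode must be 'relative' or 'absolute'")
    gene_index = {g: i for i, g in enumerate(np.asarray(gene_ids))}
    missing = [g for g in up_genes if g not in gene_index]
    if missing:
        raise MultiomeError(f"up gene(s) absent from gene list: {missing[:5]}")
    idx = np.array([gene_index[g] for g in up_genes])

    stages = pd.Series(cells["stage"]) if hasattr(cells, "columns") else pd.Series(cells)
    pre_mask = stages.isin(pre_stages).to_numpy()
    if not pre_mask.any():
        raise MultiomeError(f"no cells in pre-meiotic stages {tuple(pre_stages)}")
    values = expr_norm.values if hasattr(expr_norm, "values") and not isinstance(
        expr_norm, (np.ndarray, pd.DataFrame)) else expr_norm
    dense = values.toarray() if sp.issparse(values) else np.asarray(values)
    pre_means = dense[pre_mask][:, idx].mean(axis=0)

    if threshold_mode == "relative":
        ref_mask = (stages == ref_stage).to_numpy()
        if not ref_mask.any():
            raise MultiomeError(f"reference stage {ref_stage!r} absent")
        ref_means = dense[ref_mask][:, idx].mean(axis=0)
        cutoff = expr_threshold * ref_means
    else:
        cutoff = np.full(len(idx), expr_threshold)
    pre_expressed = pre_means >= cutoff
    n_up = len(up_genes)
    n_pre = int(pre_expressed.sum())
    return AmplificationResult(
        n_up=n_up, n_pre=n_pre, fraction=n_pre / n_up,
        threshold_mode=threshold_mode, expr_threshold=expr_threshold,
        pre_stages=tuple(pre_stages),
    )
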