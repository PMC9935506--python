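"""End-to-end orchestration: normalize -> differential -> enrichment ->
deviations -> screening -> network -> targets -> amplification.

``run_pipeline`` executes the whole screen on an in-memory dataset (or
a simulated one) and writes every result table plus a JSON run manifest
recording seeds and thresholds.  Given identical inputs and seeds the
report bundle is byte-identical.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .datatypes import GeneAnnotation, MotifHitMatrix, MultiomeDataset, MultiomeError, STAGES
from .deviations import motif_deviations
from .differential import call_differential
from .motifs import motif_enrichment
from .network import (
    DEFAULT_PROMOTER_WINDOW,
    TFContext,
    amplification_fraction,
    build_interaction_network,
    nonnegative_motif_scores,
    promoter_peak_map,
    stage_means,
    tf_target_genes,
)
from .preprocess import filter_cells_features, normalize
from .screen import activity_shift_test, screen_core_tfs
from .simulate import SimConfig, generate_multiome, tf_map_frame


@dataclass
class PipelineConfig:
    group_a_stage: str = "preleptotene"
    group_b_stage: str = "leptotene"
    lfc_thresh: float = 0.25
    q_thresh: float = 0.05
    q_enrich: float = 0.05
    q_activity: float = 0.05
    promoter_window: int = DEFAULT_PROMOTER_WINDOW
    n_background: int = 50
    deviation_seed: int = 0
    min_counts_cell: int = 0
    min_cells_feature: int = 0
    strong_quantile: float = 0.75
    amplification_threshold: float = 0.1
    amplification_mode: str = "relative"
    network_stage: str = "leptotene"


def _stage_error(stage_name):
    def deco(fn):
        def wrapped(*args, **kwargs):
            try:
                return fn(*args, **kwargs)
            except Exception as exc:
                raise MultiomeError(
                    f"pipeline stage '{stage_name}' failed: {exc}; check the "
                    "inputs and thresholds for this stage") from exc
        return wrapped
    return deco


def run_pipeline(ds: MultiomeDataset, hits: MotifHitMatrix,
                 genes: GeneAnnotation, tf_map: pd.DataFrame,
                 config: PipelineConfig = None, outdir=None) -> dict:
    """Run the full screen; returns the result bundle as a dict.

    When ``outdir`` is given, every table is written as TSV and a JSON
    manifest records versions, seeds and thresholds.
    """
    cfg = config or PipelineConfig()
    if cfg.min_counts_cell or cfg.min_cells_feature:
        ds = filter_cells_features(ds, cfg.min_counts_cell, cfg.min_cells_feature)

    expr_norm = normalize(ds.expr, "expression")
    peaks_norm = normalize(ds.peaks_mat, "peaks")
    gene_ids = ds.genes["gene_id"].to_numpy()
    peak_ids = ds.peak_set.peak_ids

    degs = call_differential(expr_norm, ds.cells, cfg.group_a_stage,
                             cfg.group_b_stage, cfg.lfc_thresh, cfg.q_thresh,
                             feature_ids=gene_ids)
    deps = call_differential(peaks_norm, ds.cells, cfg.group_a_stage,
                             cfg.group_b_stage, cfg.lfc_thresh, cfg.q_thresh,
                             feature_ids=peak_ids)
    up_deps = deps.loc[deps["direction"] == "up", "feature_id"].tolist()
    bg_peaks = deps.loc[deps["direction"] != "up", "feature_id"].tolist()
    if not up_deps:
        raise MultiomeError(
            "pipeline stage 'enrichment' failed: no upregulated peaks were "
            "called; relax lfc/q thresholds or check the stage labels")
    enrich = motif_enrichment(hits, up_deps, bg_peaks)

    dev = motif_deviations(ds.peaks_mat, hits, n_background=cfg.n_background,
                           seed=cfg.deviation_seed)
    activity = activity_shift_test(dev, ds.cells, cfg.group_a_stage,
                                   cfg.group_b_stage, cfg.q_activity)

    evidence = screen_core_tfs(enrich, activity, degs, tf_map,
                               q_enrich=cfg.q_enrich, q_activity=cfg.q_activity)
    core_tfs = evidence.loc[evidence["is_core"], "tf_name"].tolist()

    pmap = promoter_peak_map(ds.peak_set, genes, cfg.promoter_window)
    ctx = TFContext(hits=hits, pmap=pmap, tf_map=tf_map,
                    gene_ids=gene_ids, peak_ids=peak_ids)

    dev_stage = pd.DataFrame(
        [stage_means(dev.z, ds.cells, s) for s in STAGES],
        index=list(STAGES), columns=dev.motif_ids)
    motif_means_all = nonnegative_motif_scores(dev_stage)

    network = None
    targets = {}
    if len(core_tfs) >= 2:
        s = cfg.network_stage
        expr_means = pd.Series(stage_means(expr_norm.values, ds.cells, s),
                               index=gene_ids)
        peak_means = pd.Series(stage_means(peaks_norm.values, ds.cells, s),
                               index=peak_ids)
        network = build_interaction_network(
            core_tfs, s, expr_means, motif_means_all.loc[s], peak_means, ctx,
            strong_quantile=cfg.strong_quantile)
        for tf in core_tfs:
            targets[tf] = tf_target_genes(tf, hits, pmap, ctx)

    up_genes = degs.loc[degs["direction"] == "up", "feature_id"].tolist()
    amplification = None
    if up_genes:
        amplification = amplification_fraction(
            expr_norm, ds.cells, up_genes, gene_ids,
            expr_threshold=cfg.amplification_threshold,
            threshold_mode=cfg.amplification_mode)

    manifest = {
        "package_version": __version__,
        "config": asdict(cfg),
        "n_cells": int(ds.n_cells),
        "n_genes": int(len(gene_ids)),
        "n_peaks": int(len(peak_ids)),
        "n_motifs": int(len(hits.motif_ids)),
        "n_up_degs": int((degs["direction"] == "up").sum()),
        "n_down_degs": int((degs["direction"] == "down").sum()),
        "n_up_deps": int((deps["direction"] == "up").sum()),
        "n_down_deps": int((deps["direction"] == "down").sum()),
        "core_tfs": core_tfs,
    }
    bundle = {
        "degs": degs, "deps": deps, "enrichment": enrich,
        "activity": activity, "evidence": evidence, "network": network,
        "targets": targets, "amplification": amplification,
        "manifest": manifest,
    }
    if outdir is not None:
        write_bundle(bundle, outdir)
    return bundle


def write_bundle(bundle: dict, outdir) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    def dump(df, name, float_format="%.10g"):
        if df is not None:
            df.to_csv(outdir / name, sep="\t", index=False,
                      float_format=float_format)

    dump(bundle["degs"], "degs.tsv")
    dump(bundle["deps"], "deps.tsv")
    dump(bundle["enrichment"], "enrichment.tsv")
    dump(bundle["activity"], "activity.tsv")
    dump(bundle["evidence"], "core_tf_evidence.tsv")
    dump(bundle["network"], "network_edges.tsv")
    targets = bundle.get("targets") or {}
    if targets:
        all_targets = pd.concat(targets.values(), ignore_index=True)
        dump(all_targets, "tf_targets.tsv")
    amp = bundle.get("amplification")
    manifest = dict(bundle["manifest"])
    if amp is not None:
        with open(outdir / "amplification.json", "w") as fh:
            json.dump(asdict(amp), fh, indent=1, sort_keys=True)
    with open(outdir / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)


def simulate_and_run(sim_config: SimConfig, pipeline_config: PipelineConfig = None,
                     outdir=None):
    """Simulate a multiome and run the full screen on it."""
    ds, hits, genes, truth = generate_multiome(sim_config)
    tf_map = tf_map_frame(sim_config)
    bundle = run_pipeline(ds, hits, genes, tf_map,
                          config=pipeline_config, outdir=outdir)
    return bundle, truth
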