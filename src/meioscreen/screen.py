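"""The core-TF screening framework.

A candidate TF is nominated as a *core TF* of the mitotic/meiotic
switch when three lines of evidence coincide in the
preleptotene -> leptotene comparison:

(a) its motif is enriched among upregulated differential peaks,
(b) its per-cell motif-activity deviation shifts upward, and
(c) its own gene is an upregulated differential gene.

The conjunction of the three booleans defines ``is_core``; the full
evidence (statistics behind each boolean) is retained for every
candidate, core or not.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd

from .datatypes import DeviationMatrix, MultiomeError
from .differential import bh_fdr, rank_sum_test


def activity_shift_test(dev: DeviationMatrix, cells, stage_a: str,
                        stage_b: str, q_thresh: float = 0.05) -> pd.DataFrame:
    """Per-motif shift of deviation z-scores between two stage groups.

    shift = mean(z | stage_b) - mean(z | stage_a); two-sided rank-sum
    p per motif, BH across motifs; ``upregulated`` iff shift > 0 and
    q <= ``q_thresh``.
    """
    stages = pd.Series(cells["stage"]) if hasattr(cells, "columns") else pd.Series(cells)
    present = sorted(stages.unique())
    for stage in (stage_a, stage_b):
        if stage not in set(stages):
            raise MultiomeError(f"stage {stage!r} absent; available stages: {present}")
    mask_a = (stages == stage_a).to_numpy()
    mask_b = (stages == stage_b).to_numpy()

    n_motifs = dev.z.shape[1]
    shift = np.zeros(n_motifs)
    p = np.ones(n_motifs)
    for j in range(n_motifs):
        if dev.missing[j]:
            shift[j] = np.nan
            continue
        za, zb = dev.z[mask_a, j], dev.z[mask_b, j]
        shift[j] = zb.mean() - za.mean()
        _, p[j] = rank_sum_test(za, zb)
    tested = ~dev.missing
    q = np.full(n_motifs, np.nan)
    q[tested] = bh_fdr(p[tested])
    upregulated = tested & (shift > 0) & (q <= q_thresh)
    return pd.DataFrame({
        "motif_id": dev.motif_ids,
        "shift": shift,
        "p_value": np.where(tested, p, np.nan),
        "q_value": q,
        "upregulated": upregulated,
    })


def screen_core_tfs(enrich: pd.DataFrame, activity: pd.DataFrame,
                    degs: pd.DataFrame, tf_map: pd.DataFrame,
                    q_enrich: float = 0.05, q_activity: float = 0.05,
                    top_n_enrich: int | None = None) -> pd.DataFrame:
    """Intersect the three evidence tables into core-TF calls.

    ``tf_map`` links each candidate motif to exactly one gene
    (columns motif_id, tf_name, gene_id); unmapped motifs are skipped
    with a warning.  ``top_n_enrich``, if given, additionally requires
    the motif to rank in the top N by fold enrichment.
    Output is sorted by fold enrichment, one row per candidate, with
    ``is_core`` the conjunction of the three criteria.
    """
    if len(tf_map) == 0:
        raise MultiomeError("empty candidate TF list")
    enrich = enrich.set_index("motif_id")
    activity_t = activity.set_index("motif_id")
    degs_t = degs.set_index("feature_id")

    rank_cut = None
    if top_n_enrich is not None:
        folds = enrich["fold_enrichment"].sort_values(ascending=False)
        if len(folds) > top_n_enrich:
            rank_cut = folds.iloc[top_n_enrich - 1]

    rows = []
    for _, cand in tf_map.iterrows():
        motif, tf_name, gene = cand["motif_id"], cand["tf_name"], cand["gene_id"]
        if motif not in enrich.index or motif not in activity_t.index:
            warnings.warn(f"motif {motif!r} absent from evidence tables; skipped",
                          stacklevel=2)
            continue
        if gene not in degs_t.index:
            warnings.warn(f"gene {gene!r} for motif {motif!r} absent from DEG "
                          "table; skipped", stacklevel=2)
            continue
        e = enrich.loc[motif]
        a = activity_t.loc[motif]
        d = degs_t.loc[gene]
        enriched = bool(e["q_value"] <= q_enrich and e["fold_enrichment"] > 1)
        if rank_cut is not None:
            enriched = enriched and e["fold_enrichment"] >= rank_cut
        act_up = bool(np.isfinite(a["shift"]) and np.isfinite(a["q_value"])
                      and a["shift"] > 0 and a["q_value"] <= q_activity)
        deg_up = bool(d["direction"] == "up")
        rows.append({
            "tf_name": tf_name,
            "motif_id": motif,
            "gene_id": gene,
            "enriched_in_up_deps": enriched,
            "enrich_fold": float(e["fold_enrichment"]),
            "enrich_q": float(e["q_value"]),
            "activity_up": act_up,
            "activity_shift": float(a["shift"]),
            "activity_q": float(a["q_value"]) if np.isfinite(a["q_value"]) else np.nan,
            "deg_up": deg_up,
            "deg_log2fc": float(d["log2fc"]),
            "deg_q": float(d["q_value"]),
            "is_core": enriched and act_up and deg_up,
        })
    if not rows:
        raise MultiomeError("no candidate TF could be evaluated")
    out = pd.DataFrame(rows).sort_values(
        "enrich_fold", ascending=False).reset_index(drop=True)
    return out
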