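"""Differential genes (DEGs) and differential peaks (DEPs).

One engine for both modalities: a two-sided Wilcoxon rank-sum test per
feature on normalized values, log2 fold change of group means with a
pseudocount, and Benjamini-Hochberg adjustment across all tested
features.  The rank-sum test uses exact enumeration when both groups
have n <= 8 and no ties, and the tie-corrected normal approximation
otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datatypes import MultiomeError, NormalizedMatrix


def rank_sum_test(values_a, values_b) -> tuple[float, float]:
    """Two-sided Wilcoxon rank-sum test.

    Returns ``(U_statistic, p_value)`` with the U statistic of the first
    group.  Exact enumeration when both n <= 8 and there are no ties;
    tie-corrected normal approximation otherwise.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise MultiomeError("rank_sum_test requires both groups non-empty")
    pooled = np.concatenate([a, b])
    if np.unique(pooled).size == 1:
        # every observation identical: no evidence against the null
        return float(a.size * b.size / 2.0), 1.0
    no_ties = np.unique(pooled).size == pooled.size
    if a.size <= 8 and b.size <= 8 and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method=method)
    return float(res.statistic), float(min(res.pvalue, 1.0))


def bh_fdr(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted q-values, order-preserving."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise MultiomeError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def _group_arrays(norm: NormalizedMatrix | sp.spmatrix | np.ndarray, cells,
                  stage_a: str, stage_b: str):
    values = norm.values if isinstance(norm, NormalizedMatrix) else norm
    values = sp.csr_matrix(values) if sp.issparse(values) else np.asarray(values)
    stages = pd.Series(cells["stage"]) if hasattr(cells, "columns") else pd.Series(cells)
    present = sorted(stages.unique())
    for stage in (stage_a, stage_b):
        if stage not in set(stages):
            raise MultiomeError(f"stage {stage!r} absent; available stages: {present}")
    mask_a = (stages == stage_a).to_numpy()
    mask_b = (stages == stage_b).to_numpy()
    dense = values.toarray() if sp.issparse(values) else values
    return dense[mask_a], dense[mask_b]


def call_differential(norm, cells, group_a_stage: str, group_b_stage: str,
                      lfc_thresh: float = 0.25, q_thresh: float = 0.05,
                      feature_ids=None) -> pd.DataFrame:
    """Per-feature differential table between two stage groups.

    log2fc is ``log2((mean_B + eps) / (mean_A + eps))`` on normalized
    values with ``eps = 1 / min(n_A, n_B)``; direction is ``up``/``down``
    when ``|log2fc| >= lfc_thresh`` and ``q <= q_thresh``, else ``ns``.
    """
    if lfc_thresh <= 0 or q_thresh <= 0:
        raise MultiomeError("thresholds must be > 0")
    A, B = _group_arrays(norm, cells, group_a_stage, group_b_stage)
    n_features = A.shape[1]
    if feature_ids is None:
        feature_ids = np.arange(n_features).astype(str)
    feature_ids = np.asarray(feature_ids)
    if len(feature_ids) != n_features:
        raise MultiomeError("feature_ids length does not match matrix")

    eps = 1.0 / min(A.shape[0], B.shape[0])
    mean_a = A.mean(axis=0)
    mean_b = B.mean(axis=0)
    log2fc = np.log2((mean_b + eps) / (mean_a + eps))

    # constant features carry no signal; the rank-sum z would be 0/0
    rng_span = np.vstack([A, B])
    constant = np.all(rng_span == rng_span[0], axis=0)

    small = A.shape[0] <= 8 and B.shape[0] <= 8
    if small:
        p = np.ones(n_features)
        for j in range(n_features):
            if not constant[j]:
                _, p[j] = rank_sum_test(A[:, j], B[:, j])
    else:
        with np.errstate(invalid="ignore", divide="ignore"):
            res = stats.mannwhitneyu(A, B, alternative="two-sided",
                                     method="asymptotic", axis=0)
        p = np.asarray(res.pvalue, dtype=float)
        p[constant] = 1.0
        p = np.clip(np.nan_to_num(p, nan=1.0), 0.0, 1.0)
    log2fc[constant] = 0.0

    q = bh_fdr(p)
    direction = np.where(
        (np.abs(log2fc) >= lfc_thresh) & (q <= q_thresh),
        np.where(log2fc > 0, "up", "down"),
        "ns",
    )
    direction[constant] = "ns"
    return pd.DataFrame({
        "feature_id": feature_ids,
        "log2fc": log2fc,
        "p_value": p,
        "q_value": q,
        "direction": direction,
    })
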