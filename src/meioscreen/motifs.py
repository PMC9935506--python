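"""PWM motif models, scanning, and enrichment in differential peaks.

The scanner scores every window of a sequence on both strands with a
log-odds (base 2) score against background base frequencies, with a
small pseudocount on PWM entries; a peak "hit" is any window scoring at
least ``threshold x max_achievable_score``.  Enrichment of a motif in a
peak set versus background peaks uses the one-sided hypergeometric
tail.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp
from scipy import stats

from .datatypes import MotifHitMatrix, MultiomeError
from .differential import bh_fdr

_BASE_INDEX = {"A": 0, "C": 1, "G": 2, "T": 3}
_PWM_PSEUDOCOUNT = 1e-3


@dataclass
class MotifModel:
    """A TF's binding preference as an L x 4 probability matrix (A,C,G,T)."""

    motif_id: str
    tf_name: str
    pwm: np.ndarray
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))

    def __post_init__(self) -> None:
        self.pwm = np.asarray(self.pwm, dtype=float)
        self.background = np.asarray(self.background, dtype=float)
        if self.pwm.ndim != 2 or self.pwm.shape[1] != 4:
            raise MultiomeError(f"motif {self.motif_id}: PWM must be L x 4")
        if self.pwm.shape[0] < 4:
            raise MultiomeError(f"motif {self.motif_id}: motif length must be >= 4")
        if not np.allclose(self.pwm.sum(axis=1), 1.0, atol=1e-6):
            raise MultiomeError(f"motif {self.motif_id}: PWM rows must sum to 1")
        if not np.isclose(self.background.sum(), 1.0, atol=1e-6):
            raise MultiomeError(f"motif {self.motif_id}: background must sum to 1")

    @property
    def length(self) -> int:
        return self.pwm.shape[0]

    def log_odds(self) -> np.ndarray:
        """L x 4 log2-odds matrix with pseudocount on PWM entries."""
        return np.log2((self.pwm + _PWM_PSEUDOCOUNT) / self.background[None, :])

    def max_score(self) -> float:
        return float(self.log_odds().max(axis=1).sum())

    def consensus(self) -> str:
        return "".join("ACGT"[i] for i in self.pwm.argmax(axis=1))


def _encode(sequence: str) -> np.ndarray:
    seq = sequence.upper()
    codes = np.full(len(seq), -1, dtype=np.int8)
    for base, idx in _BASE_INDEX.items():
        codes[np.frombuffer(seq.encode(), dtype="S1") == base.encode()] = idx
    bad = set(seq) - set("ACGTN")
    if bad:
        raise MultiomeError(f"sequence contains invalid characters {sorted(bad)}")
    return codes


def _revcomp(sequence: str) -> str:
    comp = str.maketrans("ACGTN", "TGCAN")
    return sequence.upper().translate(comp)[::-1]


def scan_pwm(motif: MotifModel, sequence: str, score_threshold: float = 0.8) -> pd.DataFrame:
    """Scan a sequence on both strands for motif matches.

    ``score_threshold`` is a fraction of the maximum achievable log-odds
    score, in (0, 1].  Windows containing N are skipped.  Returns a table
    (position, strand, score); ``position`` is the 0-based start of the
    window on the forward strand for both strands.
    """
    if not (0 < score_threshold <= 1):
        raise MultiomeError("score_threshold must be in (0, 1]")
    L = motif.length
    lo = motif.log_odds()
    cutoff = score_threshold * motif.max_score()
    rows = []
    for strand, seq in (("+", sequence), ("-", _revcomp(sequence))):
        codes = _encode(seq)
        n = len(codes) - L + 1
        if n <= 0:
            continue
        windows = np.lib.stride_tricks.sliding_window_view(codes, L)
        valid = (windows >= 0).all(axis=1)
        scores = np.zeros(n)
        idx = np.flatnonzero(valid)
        if idx.size:
            w = windows[idx]
            scores[idx] = lo[np.arange(L)[None, :], w].sum(axis=1)
        for i in idx:
            if scores[i] >= cutoff:
                pos = i if strand == "+" else len(sequence) - L - i
                rows.append((int(pos), strand, float(scores[i])))
    return (pd.DataFrame(rows, columns=["position", "strand", "score"])
            .sort_values(["position", "strand"]).reset_index(drop=True))


def scan_peaks(motifs: list[MotifModel], sequences: dict[str, str],
               peak_ids, score_threshold: float = 0.8) -> MotifHitMatrix:
    """Build a MotifHitMatrix by scanning per-peak sequences."""
    peak_ids = np.asarray(peak_ids)
    motif_ids = np.asarray([m.motif_id for m in motifs])
    hits = sp.lil_matrix((len(peak_ids), len(motifs)))
    scores = sp.lil_matrix((len(peak_ids), len(motifs)))
    for i, pid in enumerate(peak_ids):
        seq = sequences.get(pid, "")
        for j, motif in enumerate(motifs):
            found = scan_pwm(motif, seq, score_threshold) if seq else None
            if found is not None and len(found):
                hits[i, j] = 1.0
                scores[i, j] = found["score"].max()
    return MotifHitMatrix(hits=hits.tocsr(), scores=scores.tocsr(),
                          peak_ids=peak_ids, motif_ids=motif_ids)


def motif_enrichment(hits: MotifHitMatrix, set_peaks, background_peaks) -> pd.DataFrame:
    """Motif over-representation in ``set_peaks`` versus background.

    ``set_peaks`` and ``background_peaks`` are disjoint iterables of
    peak ids.  Per motif: fold enrichment of hit rates and a one-sided
    hypergeometric tail p-value for drawing at least the observed number
    of hits into the set from the pooled peaks; BH q across motifs.
    """
    set_peaks = list(set_peaks)
    background_peaks = list(background_peaks)
    if not set_peaks or not background_peaks:
        raise MultiomeError("set and background peak lists must be non-empty")
    overlap = set(set_peaks) & set(background_peaks)
    if overlap:
        raise MultiomeError(
            f"set and background overlap on {len(overlap)} peak(s)")
    index = {p: i for i, p in enumerate(hits.peak_ids)}
    missing = [p for p in set_peaks + background_peaks if p not in index]
    if missing:
        raise MultiomeError(f"peak(s) absent from hit matrix: {missing[:5]}")
    set_idx = np.array([index[p] for p in set_peaks])
    bg_idx = np.array([index[p] for p in background_peaks])

    H = hits.hits
    k_set = np.asarray(H[set_idx].sum(axis=0)).ravel()
    k_bg = np.asarray(H[bg_idx].sum(axis=0)).ravel()
    n_set, n_bg = len(set_idx), len(bg_idx)
    M = n_set + n_bg
    K = k_set + k_bg

    rate_set = k_set / n_set
    rate_bg = k_bg / n_bg
    with np.errstate(divide="ignore", invalid="ignore"):
        fold = np.where(rate_bg > 0, rate_set / rate_bg,
                        np.where(rate_set > 0, np.inf, 0.0))
    # P[X >= k_set] drawing n_set peaks from M with K total hits
    p = stats.hypergeom.sf(k_set - 1, M, K, n_set)
    p = np.clip(p, 0.0, 1.0)
    q = bh_fdr(p)
    return pd.DataFrame({
        "motif_id": hits.motif_ids,
        "n_hits_in_set": k_set.astype(int),
        "n_set": n_set,
        "n_hits_background": k_bg.astype(int),
        "n_background": n_bg,
        "fold_enrichment": fold,
        "p_value": p,
        "q_value": q,
    })
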