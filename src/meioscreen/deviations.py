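"""Per-cell motif-activity deviations (bias-matched z-scores).

For each motif, the observed accessibility of a cell over the motif's
peak set is compared with the expectation under that cell's sequencing
depth and the peak set's share of total accessibility:

    raw(cell, motif) = obs(cell, motif) - depth(cell) * share(motif)

The raw deviation is then standardized, per cell, against ``n_background``
random peak sets matched to the motif's peak set on mean accessibility
(decile-binned matching, sampled with replacement within bins):

    z = (raw - mean_bg) / sd_bg

This is a simplified bias-matched deviation: background sets are matched
on accessibility only (the synthetic peaks carry no sequence, so there
is no GC dimension to match).  Deterministic given the seed.
"""

from __future__ import annotations

import warnings

import numpy as np
import scipy.sparse as sp
from sklearn.base import BaseEstimator, TransformerMixin

from .datatypes import DeviationMatrix, MotifHitMatrix, MultiomeError


class MotifDeviationScorer(BaseEstimator, TransformerMixin):
    """Sklearn-style transformer mapping peak counts to motif deviation z-scores.

    Parameters
    ----------
    hits:
        Peaks x motifs hit matrix; column order defines output order.
    n_background:
        Number of accessibility-matched background peak sets per motif.
    n_bins:
        Number of accessibility bins used for matching.
    seed:
        Seed for background-set sampling.
    """

    def __init__(self, hits: MotifHitMatrix = None, n_background: int = 50,
                 n_bins: int = 10, seed: int = 0):
        self.hits = hits
        self.n_background = n_background
        self.n_bins = n_bins
        self.seed = seed

    def fit(self, X, y=None):
        """Learn accessibility bins and sample background peak sets from X."""
        if self.hits is None:
            raise MultiomeError("MotifDeviationScorer requires a hit matrix")
        if self.n_background < 10:
            raise MultiomeError("n_background must be >= 10")
        X = sp.csr_matrix(X, dtype=float)
        n_peaks = X.shape[1]
        if n_peaks != self.hits.hits.shape[0]:
            raise MultiomeError(
                f"peak matrix has {n_peaks} peaks but hit matrix has "
                f"{self.hits.hits.shape[0]}"
            )
        rng = np.random.default_rng(self.seed)
        mean_acc = np.asarray(X.mean(axis=0)).ravel()
        # decile bins on mean accessibility; the key is normalized by the
        # grand mean and rounded so binning is invariant to global count
        # scaling, with ties broken deterministically by column index
        grand = mean_acc.mean()
        key = np.round(mean_acc / grand, 9) if grand > 0 else mean_acc
        order = np.lexsort((np.arange(n_peaks), key))
        bins = np.empty(n_peaks, dtype=int)
        bins[order] = np.minimum(
            (np.arange(n_peaks) * self.n_bins) // n_peaks, self.n_bins - 1
        )
        bin_members = [np.flatnonzero(bins == b) for b in range(self.n_bins)]

        H = self.hits.hits.tocsc()
        n_motifs = H.shape[1]
        self.motif_peak_sets_ = []
        self.background_sets_ = []
        self.missing_ = np.zeros(n_motifs, dtype=bool)
        for j in range(n_motifs):
            peaks_j = H.indices[H.indptr[j]:H.indptr[j + 1]]
            self.motif_peak_sets_.append(peaks_j)
            if peaks_j.size == 0:
                self.missing_[j] = True
                self.background_sets_.append(None)
                continue
            counts = np.bincount(bins[peaks_j], minlength=self.n_bins)
            sets = np.empty((self.n_background, peaks_j.size), dtype=int)
            for s in range(self.n_background):
                pieces = [
                    rng.choice(bin_members[b], size=int(c), replace=True)
                    for b, c in enumerate(counts) if c > 0
                ]
                sets[s] = np.concatenate(pieces)
            self.background_sets_.append(sets)
        self.bins_ = bins
        self.n_peaks_in_ = n_peaks
        return self

    def transform(self, X) -> DeviationMatrix:
        if not hasattr(self, "background_sets_"):
            raise MultiomeError("MotifDeviationScorer must be fit before transform")
        X = sp.csr_matrix(X, dtype=float)
        if X.shape[1] != self.n_peaks_in_:
            raise MultiomeError("peak dimension changed between fit and transform")
        depth = np.asarray(X.sum(axis=1)).ravel()
        total = depth.sum()
        peak_totals = np.asarray(X.sum(axis=0)).ravel()
        n_cells = X.shape[0]
        n_motifs = len(self.motif_peak_sets_)
        z = np.zeros((n_cells, n_motifs))
        raw_out = np.zeros((n_cells, n_motifs))

        if total <= 0:
            return DeviationMatrix(z=z, raw=raw_out,
                                   motif_ids=self.hits.motif_ids,
                                   n_background=self.n_background,
                                   seed=self.seed, missing=self.missing_.copy())

        def raw_dev(indicator: sp.csr_matrix) -> np.ndarray:
            # indicator: peaks x k (columns are peak sets, entries multiplicities)
            obs = np.asarray((X @ indicator).todense())
            share = (peak_totals @ indicator) / total
            return obs - np.outer(depth, share)

        for j in range(n_motifs):
            if self.missing_[j]:
                warnings.warn(
                    f"motif {self.hits.motif_ids[j]!r} has no hit peaks; "
                    "deviation undefined", stacklevel=2)
                z[:, j] = np.nan
                raw_out[:, j] = np.nan
                continue
            peaks_j = self.motif_peak_sets_[j]
            bg = self.background_sets_[j]
            k = peaks_j.size
            cols = [peaks_j] + [bg[s] for s in range(self.n_background)]
            col_idx = np.concatenate([np.full(c.size, i) for i, c in enumerate(cols)])
            row_idx = np.concatenate(cols)
            indicator = sp.csr_matrix(
                (np.ones(row_idx.size), (row_idx, col_idx)),
                shape=(self.n_peaks_in_, 1 + self.n_background),
            )
            devs = raw_dev(indicator)
            raw_j = devs[:, 0]
            bg_devs = devs[:, 1:]
            mean_bg = bg_devs.mean(axis=1)
            sd_bg = bg_devs.std(axis=1, ddof=1)
            raw_out[:, j] = raw_j
            with np.errstate(invalid="ignore", divide="ignore"):
                zj = (raw_j - mean_bg) / sd_bg
            z[:, j] = np.where(sd_bg > 0, zj, 0.0)
        return DeviationMatrix(z=z, raw=raw_out, motif_ids=self.hits.motif_ids,
                               n_background=self.n_background, seed=self.seed,
                               missing=self.missing_.copy())


def motif_deviations(peak_counts, hits: MotifHitMatrix, n_background: int = 50,
                     seed: int = 0, n_bins: int = 10) -> DeviationMatrix:
    """Convenience wrapper: fit and apply :class:`MotifDeviationScorer`."""
    scorer = MotifDeviationScorer(hits=hits, n_background=n_background,
                                  n_bins=n_bins, seed=seed)
    return scorer.fit(peak_counts).transform(peak_counts)
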