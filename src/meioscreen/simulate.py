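"""Stage-structured synthetic multiome generator with planted ground truth.

The generator emulates the statistical structure a core-TF screen needs
to be testable end-to-end without any sequencing data:

* negative-binomial transcript counts with stage-dependent means over
  the five germ-cell stages (mitotic, transition, preleptotene,
  leptotene, zygotene);
* Poisson peak counts with planted up-/down-differential peaks in the
  leptotene-vs-preleptotene comparison;
* Bernoulli motif hits with planted enrichment of core-TF motifs in
  up-differential peaks;
* planted core TFs satisfying all three screening criteria and decoy
  TFs each violating exactly one of them;
* planted TF1 -> TF2 regulatory edges realized as accessible,
  motif-bearing peaks inside the TF2 promoter window; and
* a configurable fraction of leptotene-upregulated genes already
  expressed before meiotic initiation (the transcriptional
  amplification structure).

All randomness flows through one seeded :func:`numpy.random.default_rng`
generator, so identical configurations produce bit-identical output.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field

import numpy as np
import pandas as pd
import scipy.sparse as sp

from .datatypes import (
    GeneAnnotation,
    MotifHitMatrix,
    MultiomeDataset,
    MultiomeError,
    PeakSet,
    STAGES,
)

# genome layout constants (one chromosome per ~100 genes, fixed tiling)
_GENES_PER_CHROM = 100
_GENE_SPACING = 50_000
_GENE_OFFSET = 10_000
_GENE_LENGTH = 2_000
_PEAK_WIDTH = 500
_PROMOTER_JITTER = 2_500     # promoter peak centre within TSS +/- this
_DISTAL_MIN = 25_000         # distal peak offsets within the gene slot
_DISTAL_MAX = 47_000


@dataclass
class SimConfig:
    """Study conditions of the synthetic multiome.

    Defaults mirror a scaled-down embryonic-ovary experiment: 300 cells
    per stage, 2,000 genes, 5,000 peaks, 120 candidate TF motifs of
    which 14 are planted core TFs, log2 effect 2 for upregulation,
    4-fold odds of core-TF motifs in up-differential peaks, and 85% of
    upregulated genes already expressed pre-meiotically.
    """

    n_cells_per_stage: int = 300
    n_genes: int = 2000
    n_peaks: int = 5000
    n_motifs: int = 120
    n_core_tfs: int = 14
    n_decoy_tfs: int = 12              # split evenly across the three criteria
    lfc_core_expr: float = 2.0
    lfc_de_genes: float = 2.0
    frac_de_genes: float = 0.3
    frac_de_peaks: float = 0.3
    accessibility_effect: float = 2.0  # log2 change of differential peaks
    motif_enrich_odds: float = 4.0
    motif_base_prob: float = 0.05
    n_planted_edges: int = 20
    tf_promoter_motif_prob: float = 0.35  # motif density at core-TF promoters
    amplification_fraction: float = 0.85
    pre_expression_level: float = 2.0  # NB mean floor for pre-expressed genes
    nb_dispersion: float = 0.5         # var = mu + dispersion * mu^2
    expr_depth: float = 1.0
    peak_depth: float = 1.0
    frac_weak_peaks: float = 0.15      # planted sub-threshold gainers
    weak_gain_lfc: float = 0.3
    seed: int = 0

    def validate(self) -> "SimConfig":
        counts = dict(n_cells_per_stage=self.n_cells_per_stage,
                      n_genes=self.n_genes, n_peaks=self.n_peaks,
                      n_motifs=self.n_motifs)
        for name, v in counts.items():
            if v <= 0:
                raise MultiomeError(f"{name} must be positive")
        for name in ("frac_de_genes", "frac_de_peaks", "amplification_fraction",
                     "motif_base_prob", "frac_weak_peaks"):
            v = getattr(self, name)
            if not (0 <= v <= 1):
                raise MultiomeError(f"{name} must be in [0, 1]")
        if self.motif_enrich_odds < 1:
            raise MultiomeError("motif_enrich_odds must be >= 1")
        if self.n_core_tfs < 0 or self.n_decoy_tfs < 0:
            raise MultiomeError("TF counts must be >= 0")
        if self.n_core_tfs + self.n_decoy_tfs > self.n_motifs:
            raise MultiomeError("core + decoy TFs exceed n_motifs")
        if self.n_motifs > self.n_genes:
            raise MultiomeError("need at least one gene per motif")
        if self.n_planted_edges > max(0, self.n_core_tfs * (self.n_core_tfs - 1)):
            raise MultiomeError(
                f"n_planted_edges={self.n_planted_edges} exceeds the number of "
                f"ordered non-self core-TF pairs "
                f"({self.n_core_tfs * (self.n_core_tfs - 1)})")
        n_distal = self.n_peaks - self.n_genes if self.n_peaks > self.n_genes else 0
        n_struct = (2 * round(self.frac_de_peaks * self.n_peaks / 2)
                    + round(self.frac_weak_peaks * self.n_peaks))
        if n_struct > n_distal:
            raise MultiomeError(
                "not enough distal peaks for the requested differential and "
                f"weak-gain structure ({n_struct} needed, {n_distal} available); "
                "increase n_peaks or lower frac_de_peaks/frac_weak_peaks")
        return self


@dataclass
class PlantedTruth:
    """Ground-truth record of everything the generator planted."""

    core_tf_ids: list
    decoy_tf_ids: dict            # tf_name -> criterion it fails
    up_deg_ids: list
    down_deg_ids: list
    up_dep_ids: list
    down_dep_ids: list
    weak_peak_ids: list
    planted_edges: list           # (tf_from, tf_to, promoter_peak_id)
    preexpressed_up_gene_ids: list
    config: dict = field(default_factory=dict)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(asdict(self), fh, indent=1, sort_keys=True)

    @classmethod
    def from_json(cls, path) -> "PlantedTruth":
        with open(path) as fh:
            d = json.load(fh)
        d["planted_edges"] = [tuple(e) for e in d["planted_edges"]]
        return cls(**d)


def _odds_boost(p: float, odds_mult: float) -> float:
    """Multiply the odds of a Bernoulli probability."""
    odds = odds_mult * p / (1 - p)
    return odds / (1 + odds)


def _nb_counts(rng: np.random.Generator, mean: np.ndarray,
               dispersion: float) -> np.ndarray:
    """Gamma-Poisson (negative binomial) counts, var = mu + dispersion*mu^2."""
    mean = np.maximum(mean, 1e-12)
    if dispersion <= 0:
        return rng.poisson(mean)
    shape = 1.0 / dispersion
    lam = rng.gamma(shape, mean * dispersion)
    return rng.poisson(lam)


def generate_multiome(config: SimConfig):
    """Draw one synthetic multiome.

    Returns ``(MultiomeDataset, MotifHitMatrix, GeneAnnotation,
    PlantedTruth)`` plus a motif->gene map stored on the truth record's
    config (also reachable via :func:`tf_map_frame`).
    """
    cfg = config.validate()
    rng = np.random.default_rng(cfg.seed)

    n_stages = len(STAGES)
    n_cells = cfg.n_cells_per_stage * n_stages
    stage_of_cell = np.repeat(np.arange(n_stages), cfg.n_cells_per_stage)

    # --- identities -------------------------------------------------------
    gene_ids = np.array(
        [f"TF{i:03d}" if i < cfg.n_motifs else f"G{i:05d}"
         for i in range(cfg.n_genes)])
    motif_ids = np.array([f"M{i:03d}" for i in range(cfg.n_motifs)])
    tf_names = gene_ids[: cfg.n_motifs]

    core_idx = np.arange(cfg.n_core_tfs)
    per_type = cfg.n_decoy_tfs // 3
    rem = cfg.n_decoy_tfs - 3 * per_type
    sizes = [per_type + (1 if t < rem else 0) for t in range(3)]
    d0 = cfg.n_core_tfs
    decoy_deg_idx = np.arange(d0, d0 + sizes[0])                    # fails DEG
    decoy_enr_idx = np.arange(d0 + sizes[0], d0 + sizes[0] + sizes[1])  # fails enrichment
    decoy_act_idx = np.arange(d0 + sizes[0] + sizes[1], d0 + cfg.n_decoy_tfs)  # fails activity

    # --- genome layout ----------------------------------------------------
    gene_slot = np.arange(cfg.n_genes) % _GENES_PER_CHROM
    gene_chrom = np.array(
        [f"chr{1 + i // _GENES_PER_CHROM}" for i in range(cfg.n_genes)])
    gene_start = gene_slot * _GENE_SPACING + _GENE_OFFSET
    gene_end = gene_start + _GENE_LENGTH
    strand = rng.choice(["+", "-"], size=cfg.n_genes)
    tss = np.where(strand == "+", gene_start, gene_end)
    genes = GeneAnnotation(pd.DataFrame({
        "gene_id": gene_ids, "chrom": gene_chrom, "strand": strand,
        "start": gene_start, "end": gene_end,
    })).validate()

    # planted edge pairs (peaks for them are placed below)
    edge_pairs: list[tuple[int, int]] = []
    if cfg.n_planted_edges and cfg.n_core_tfs >= 2:
        pairs = [(int(a), int(b)) for a in core_idx for b in core_idx if a != b]
        chosen = rng.choice(len(pairs), size=cfg.n_planted_edges, replace=False)
        edge_pairs = [pairs[int(c)] for c in chosen]
    edge_targets = sorted({b for _, b in edge_pairs})

    # one promoter peak per gene plus one dedicated promoter-window peak
    # per planted-edge target, centres within TSS +/- _PROMOTER_JITTER
    n_promoter = min(cfg.n_genes, cfg.n_peaks - len(edge_targets))
    if n_promoter < cfg.n_motifs:
        raise MultiomeError("n_peaks too small for promoter peaks of all TFs")
    centre = tss[:n_promoter] + rng.integers(
        -_PROMOTER_JITTER, _PROMOTER_JITTER + 1, size=n_promoter)
    prom_start = np.maximum(0, centre - _PEAK_WIDTH // 2)
    prom_end = prom_start + _PEAK_WIDTH
    n_distal = cfg.n_peaks - n_promoter - len(edge_targets)
    distal_gene = rng.integers(0, cfg.n_genes, size=n_distal)
    distal_start = (gene_slot[distal_gene] * _GENE_SPACING
                    + rng.integers(_DISTAL_MIN, _DISTAL_MAX, size=n_distal))
    et = np.array(edge_targets, dtype=int)
    edge_centre = tss[et] + rng.integers(
        -_PROMOTER_JITTER, _PROMOTER_JITTER + 1, size=len(et)) if len(et) else np.array([], dtype=int)
    edge_start = np.maximum(0, edge_centre - _PEAK_WIDTH // 2).astype(int)
    peak_chrom = np.concatenate([gene_chrom[:n_promoter], gene_chrom[distal_gene],
                                 gene_chrom[et]])
    peak_start = np.concatenate([prom_start, distal_start, edge_start])
    peak_end = np.concatenate([prom_end, distal_start + _PEAK_WIDTH,
                               edge_start + _PEAK_WIDTH])
    peak_ids = np.array([f"P{i:05d}" for i in range(cfg.n_peaks)])
    peak_set = PeakSet(pd.DataFrame({
        "peak_id": peak_ids, "chrom": peak_chrom,
        "start": peak_start.astype(int), "end": peak_end.astype(int),
    })).validate()
    edge_peak_rows = np.arange(n_promoter + n_distal, cfg.n_peaks)
    edge_peak_of_target = {int(g): int(r) for g, r in zip(et, edge_peak_rows)}
    planted_edges = [(str(tf_names[a]), str(tf_names[b]),
                      str(peak_ids[edge_peak_of_target[b]]))
                     for a, b in edge_pairs]

    # --- planted peak roles (distal only) ---------------------------------
    distal_idx = np.arange(n_promoter, n_promoter + n_distal)
    n_up_dep = round(cfg.frac_de_peaks * cfg.n_peaks / 2)
    n_down_dep = n_up_dep
    n_weak = round(cfg.frac_weak_peaks * cfg.n_peaks)
    if n_up_dep + n_down_dep + n_weak > n_distal:
        raise MultiomeError("not enough distal peaks for the planted structure")
    shuffled = rng.permutation(distal_idx)
    up_dep_idx = np.sort(shuffled[:n_up_dep])
    down_dep_idx = np.sort(shuffled[n_up_dep:n_up_dep + n_down_dep])
    weak_idx = np.sort(shuffled[n_up_dep + n_down_dep:
                                n_up_dep + n_down_dep + n_weak])

    # --- expression design ------------------------------------------------
    de_on = cfg.lfc_de_genes > 0
    non_tf = np.arange(cfg.n_motifs, cfg.n_genes)
    n_up_extra = round(cfg.frac_de_genes * cfg.n_genes / 2) if de_on else 0
    n_down = round(cfg.frac_de_genes * cfg.n_genes / 2) if de_on else 0
    shuffled_genes = rng.permutation(non_tf)
    up_extra = shuffled_genes[:n_up_extra]
    down_genes = np.sort(shuffled_genes[n_up_extra:n_up_extra + n_down])

    # core TFs are planted up-DEGs whenever their own effect is positive,
    # even if the bulk DE fraction is zero; decoys of the enrichment- and
    # activity-failing types need their gene upregulated (criterion c holds)
    up_tf_parts = []
    if cfg.lfc_core_expr > 0:
        up_tf_parts.append(core_idx)
    if de_on:
        up_tf_parts.append(decoy_enr_idx)
        up_tf_parts.append(decoy_act_idx)
    up_tf = (np.concatenate(up_tf_parts).astype(int)
             if up_tf_parts else np.array([], dtype=int))
    up_gene_idx = np.sort(np.concatenate([up_tf, up_extra])).astype(int)

    base = cfg.pre_expression_level * rng.lognormal(0.0, 0.6, size=cfg.n_genes)
    lfc_gene = np.zeros(cfg.n_genes)
    lfc_gene[up_gene_idx] = cfg.lfc_de_genes
    lfc_gene[core_idx] = cfg.lfc_core_expr
    lfc_gene[down_genes] = -cfg.lfc_de_genes
    up_gene_idx = up_gene_idx[lfc_gene[up_gene_idx] > 0]

    # amplification structure: a fraction of up genes pre-expressed
    n_up = len(up_gene_idx)
    n_pre = round(cfg.amplification_fraction * n_up)
    pre_choice = rng.permutation(n_up)
    pre_idx = np.sort(up_gene_idx[pre_choice[:n_pre]])
    off_idx = np.sort(up_gene_idx[pre_choice[n_pre:]])
    base[pre_idx] = np.maximum(base[pre_idx], cfg.pre_expression_level)

    # stage-mean matrix: stages x genes
    stage_mean = np.tile(base, (n_stages, 1))
    lep, zyg = STAGES.index("leptotene"), STAGES.index("zygotene")
    mit, trans = STAGES.index("mitotic"), STAGES.index("transition")
    up_mult = 2.0 ** lfc_gene[up_gene_idx]
    stage_mean[lep, up_gene_idx] = base[up_gene_idx] * up_mult
    stage_mean[zyg, up_gene_idx] = base[up_gene_idx] * up_mult
    stage_mean[mit, off_idx] = 0.01
    stage_mean[trans, off_idx] = 0.01
    stage_mean[lep, down_genes] = base[down_genes] * 2.0 ** (-cfg.lfc_de_genes)
    stage_mean[zyg, down_genes] = base[down_genes] * 2.0 ** (-cfg.lfc_de_genes)

    cell_factor = rng.lognormal(0.0, 0.3, size=n_cells)
    expr_mean = (cell_factor[:, None] * stage_mean[stage_of_cell]
                 * cfg.expr_depth)
    expr = sp.csr_matrix(_nb_counts(rng, expr_mean, cfg.nb_dispersion))

    # --- peak accessibility design ---------------------------------------
    acc = 2.0 ** cfg.accessibility_effect
    peak_base = 0.3 * rng.lognormal(0.0, 0.5, size=cfg.n_peaks) * cfg.peak_depth
    peak_stage_mult = np.ones((n_stages, cfg.n_peaks))
    peak_stage_mult[lep, up_dep_idx] = acc
    peak_stage_mult[zyg, up_dep_idx] = acc
    # down-DEPs start high and fall, so per-hit gain/loss is symmetric
    peak_stage_mult[:, down_dep_idx] = acc
    peak_stage_mult[lep, down_dep_idx] = 1.0
    peak_stage_mult[zyg, down_dep_idx] = 1.0
    weak = 2.0 ** cfg.weak_gain_lfc
    peak_stage_mult[lep, weak_idx] = weak
    peak_stage_mult[zyg, weak_idx] = weak
    if edge_peak_rows.size:
        peak_base[edge_peak_rows] *= 2.0
        peak_stage_mult[lep, edge_peak_rows] = acc
        peak_stage_mult[zyg, edge_peak_rows] = acc

    peak_cell_factor = rng.lognormal(0.0, 0.3, size=n_cells)
    peaks_mean = (peak_cell_factor[:, None]
                  * (peak_base[None, :] * peak_stage_mult[stage_of_cell]))
    peaks_mat = sp.csr_matrix(rng.poisson(peaks_mean))

    # --- motif hits -------------------------------------------------------
    p0 = cfg.motif_base_prob
    prob = np.full((cfg.n_peaks, cfg.n_motifs), p0)
    boosted = np.concatenate([core_idx, decoy_deg_idx, decoy_act_idx])
    if boosted.size:
        prob[np.ix_(up_dep_idx, boosted)] = _odds_boost(p0, cfg.motif_enrich_odds)
    if decoy_act_idx.size:
        prob[np.ix_(down_dep_idx, decoy_act_idx)] = _odds_boost(
            p0, 2.0 * cfg.motif_enrich_odds)
    if decoy_enr_idx.size:
        prob[np.ix_(weak_idx, decoy_enr_idx)] = _odds_boost(
            p0, 10.0 * cfg.motif_enrich_odds)
        # keep these motifs out of the strong DEPs so their activity shift
        # is carried by the weak gainers alone (single-criterion failure)
        strong = np.concatenate([up_dep_idx, down_dep_idx])
        prob[np.ix_(strong, decoy_enr_idx)] = p0 / 5.0
    # TF promoters are motif-dense: core motifs occur at core-TF promoter
    # peaks at an elevated chance rate, giving the interaction network a
    # realistic population of weak (non-planted) edges
    if cfg.n_core_tfs and n_promoter > core_idx.max(initial=-1):
        prob[np.ix_(core_idx, core_idx)] = cfg.tf_promoter_motif_prob
    hits_dense = (rng.random((cfg.n_peaks, cfg.n_motifs)) < prob)
    # planted edges: silence chance core-motif hits on every edge peak first,
    # then force the regulators' motifs, so edges are unambiguous ground truth
    # (several edges may share one target promoter peak)
    for row in edge_peak_rows:
        hits_dense[row, core_idx] = False
    for tf_from, tf_to, pk in planted_edges:
        row = int(np.flatnonzero(peak_ids == pk)[0])
        j_from = int(np.flatnonzero(tf_names == tf_from)[0])
        hits_dense[row, j_from] = True
    hit_scores = np.where(hits_dense, np.round(rng.uniform(6.0, 12.0,
                          size=hits_dense.shape), 4), 0.0)
    hits = MotifHitMatrix(
        hits=sp.csr_matrix(hits_dense.astype(float)),
        scores=sp.csr_matrix(hit_scores),
        peak_ids=peak_ids, motif_ids=motif_ids,
    )

    # --- assemble ---------------------------------------------------------
    stage_labels = np.array(STAGES)[stage_of_cell]
    day = {"mitotic": "E11.5", "transition": "E12.5"}
    cells = pd.DataFrame({
        "cell_id": [f"cell{c:05d}" for c in range(n_cells)],
        "stage": stage_labels,
        "embryonic_day": [day.get(s, "E13.5") for s in stage_labels],
    })
    ds = MultiomeDataset(
        expr=expr, peaks_mat=peaks_mat, cells=cells,
        genes=pd.DataFrame({"gene_id": gene_ids}), peak_set=peak_set,
    ).validate()

    decoys = {}
    for i in decoy_deg_idx:
        decoys[str(tf_names[i])] = "deg"
    for i in decoy_enr_idx:
        decoys[str(tf_names[i])] = "enrichment"
    for i in decoy_act_idx:
        decoys[str(tf_names[i])] = "activity"

    truth = PlantedTruth(
        core_tf_ids=[str(t) for t in tf_names[core_idx]],
        decoy_tf_ids=decoys,
        up_deg_ids=[str(g) for g in gene_ids[up_gene_idx]],
        down_deg_ids=[str(g) for g in gene_ids[down_genes]],
        up_dep_ids=[str(p) for p in peak_ids[up_dep_idx]],
        down_dep_ids=[str(p) for p in peak_ids[down_dep_idx]],
        weak_peak_ids=[str(p) for p in peak_ids[weak_idx]],
        planted_edges=planted_edges,
        preexpressed_up_gene_ids=[str(g) for g in gene_ids[pre_idx]],
        config=asdict(cfg),
    )
    return ds, hits, genes, truth


def tf_map_frame(truth_or_config) -> pd.DataFrame:
    """Motif->gene candidate map implied by the generator's naming scheme."""
    cfg = truth_or_config
    if isinstance(cfg, PlantedTruth):
        cfg = SimConfig(**cfg.config)
    return pd.DataFrame({
        "motif_id": [f"M{i:03d}" for i in range(cfg.n_motifs)],
        "tf_name": [f"TF{i:03d}" for i in range(cfg.n_motifs)],
        "gene_id": [f"TF{i:03d}" for i in range(cfg.n_motifs)],
    })
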