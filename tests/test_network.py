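import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from meioscreen import (
    GeneAnnotation,
    MotifHitMatrix,
    MultiomeError,
    PeakSet,
    TFContext,
    amplification_fraction,
    build_interaction_network,
    interaction_score,
    promoter_peak_map,
    stage_means,
    tf_target_genes,
)


def _genes(rows):
    return GeneAnnotation(pd.DataFrame(
        rows, columns=["gene_id", "chrom", "strand", "start", "end"])).validate()


def _peaks(rows):
    return PeakSet(pd.DataFrame(
        rows, columns=["peak_id", "chrom", "start", "end"])).validate()


# ---------------------------------------------------------------------------
# promoter mapping
# ---------------------------------------------------------------------------

def test_peak_containing_tss_is_mapped():
    genes = _genes([("g0", "chr1", "+", 5000, 7000)])
    peaks = _peaks([("p0", "chr1", 5000, 5200)])
    assert promoter_peak_map(peaks, genes, 3000)["g0"] == ["p0"]


def test_promoter_window_boundary_is_half_open():
    tss = 5000
    genes = _genes([("g0", "chr1", "+", tss, tss + 1000)])
    peaks = _peaks([("p_at_edge", "chr1", tss + 3000, tss + 3500),
                    ("p_inside", "chr1", tss + 2999, tss + 3400)])
    out = promoter_peak_map(peaks, genes, 3000)
    assert out["g0"] == ["p_inside"]


def test_window_zero_maps_only_peaks_containing_tss_base():
    genes = _genes([("g0", "chr1", "+", 5000, 6000)])
    peaks = _peaks([("p_cover", "chr1", 4990, 5001),
                    ("p_end_at_tss", "chr1", 4900, 5000)])
    out = promoter_peak_map(peaks, genes, 0)
    assert out["g0"] == ["p_cover"]


def test_promoter_map_matches_quadratic_overlap_oracle():
    rng = np.random.default_rng(40)
    genes = _genes([(f"g{i}", f"chr{1 + i % 3}", "+" if i % 2 else "-",
                     int(s), int(s) + 2000)
                    for i, s in enumerate(rng.integers(10_000, 500_000, size=50))])
    peaks = _peaks([(f"p{i}", f"chr{1 + rng.integers(0, 3)}", int(s), int(s) + 400)
                    for i, s in enumerate(rng.integers(0, 520_000, size=500))])
    w = 3000
    got = promoter_peak_map(peaks, genes, w)
    for _, g in genes.table.iterrows():
        lo, hi = g["tss"] - w, g["tss"] + w
        expected = sorted(
            p["peak_id"] for _, p in peaks.table.iterrows()
            if p["chrom"] == g["chrom"] and p["start"] < hi and p["end"] > lo)
        assert got[g["gene_id"]] == expected


def test_unknown_chromosome_peaks_skipped_with_warning():
    genes = _genes([("g0", "chr1", "+", 5000, 6000)])
    peaks = _peaks([("p0", "chr1", 4800, 5200), ("p1", "chrUn", 10, 500)])
    with pytest.warns(UserWarning, match="skipped"):
        out = promoter_peak_map(peaks, genes, 3000)
    assert out["g0"] == ["p0"]


# ---------------------------------------------------------------------------
# stage means
# ---------------------------------------------------------------------------

def test_stage_means_single_cell_and_constant_feature():
    X = np.array([[1.0, 5.0], [3.0, 5.0], [9.0, 5.0]])
    cells = pd.DataFrame({"stage": ["mitotic", "leptotene", "leptotene"]})
    assert np.allclose(stage_means(X, cells, "mitotic"), [1.0, 5.0])
    assert np.allclose(stage_means(X, cells, "leptotene"), [6.0, 5.0])


def test_stage_means_matches_loop_oracle_on_sparse_input():
    rng = np.random.default_rng(3)
    X = rng.poisson(2.0, size=(30, 12)).astype(float)
    cells = pd.DataFrame({"stage": rng.choice(["mitotic", "leptotene"], size=30)})
    got = stage_means(sp.csr_matrix(X), cells, "leptotene")
    mask = (cells["stage"] == "leptotene").to_numpy()
    oracle = np.array([X[mask, j].mean() for j in range(12)])
    assert np.allclose(got, oracle, atol=1e-12)


# ---------------------------------------------------------------------------
# interaction scores
# ---------------------------------------------------------------------------

def _ctx_fixture():
    """Two TFs; TFA's motif hits all three promoter peaks of TFB's gene."""
    peak_ids = np.array(["p1", "p2", "p3", "p4"])
    hits = np.array([[1, 0], [1, 0], [1, 0], [0, 1]], dtype=float)
    hm = MotifHitMatrix(hits=sp.csr_matrix(hits),
                        scores=sp.csr_matrix(hits * 9.0),
                        peak_ids=peak_ids, motif_ids=np.array(["MA", "MB"]))
    tf_map = pd.DataFrame({"motif_id": ["MA", "MB"],
                           "tf_name": ["TFA", "TFB"],
                           "gene_id": ["GA", "GB"]})
    pmap = {"GA": ["p4"], "GB": ["p1", "p2", "p3"]}
    ctx = TFContext(hits=hm, pmap=pmap, tf_map=tf_map,
                    gene_ids=np.array(["GA", "GB"]), peak_ids=peak_ids)
    expr = pd.Series({"GA": 2.0, "GB": 1.0})
    motif = pd.Series({"MA": 0.5, "MB": 0.7})
    peak = pd.Series({"p1": 2.0, "p2": 3.0, "p3": 4.0, "p4": 1.0})
    return ctx, expr, motif, peak


def test_hand_built_fixture_scores_exactly_e_times_m_times_p():
    ctx, expr, motif, peak = _ctx_fixture()
    edge = interaction_score("TFA", "TFB", "leptotene", expr, motif, peak, ctx)
    assert edge.expression == 2.0
    assert edge.motif_score == 0.5
    assert edge.promoter_tn5 == 3.0      # mean of 2, 3, 4
    assert edge.score == 3.0             # 2.0 x 0.5 x 3.0
    assert edge.n_qualifying_peaks == 3


def test_zero_expression_zeroes_the_score():
    ctx, expr, motif, peak = _ctx_fixture()
    expr["GA"] = 0.0
    edge = interaction_score("TFA", "TFB", "leptotene", expr, motif, peak, ctx)
    assert edge.score == 0.0


def test_no_motif_in_target_promoter_gives_zero_p_and_score():
    ctx, expr, motif, peak = _ctx_fixture()
    # GA's only promoter peak (p4) does not carry TFA's motif
    edge = interaction_score("TFA", "TFA", "leptotene", expr, motif, peak, ctx)
    assert edge.promoter_tn5 == 0.0
    assert edge.score == 0.0


def test_unknown_tf_rejected():
    ctx, expr, motif, peak = _ctx_fixture()
    with pytest.raises(MultiomeError, match="unknown TF"):
        interaction_score("TFX", "TFB", "leptotene", expr, motif, peak, ctx)


def test_two_tfs_enumerate_four_ordered_pairs():
    ctx, expr, motif, peak = _ctx_fixture()
    net = build_interaction_network(["TFA", "TFB"], "leptotene",
                                    expr, motif, peak, ctx)
    assert len(net) == 4
    assert net["self_edge"].sum() == 2
    for row in net.itertuples():
        direct = interaction_score(row.tf_from, row.tf_to, "leptotene",
                                   expr, motif, peak, ctx)
        assert row.score == direct.score


def test_doubling_expression_doubles_outgoing_scores():
    ctx, expr, motif, peak = _ctx_fixture()
    base = build_interaction_network(["TFA", "TFB"], "leptotene",
                                     expr, motif, peak, ctx)
    doubled = build_interaction_network(["TFA", "TFB"], "leptotene",
                                        expr * 2, motif, peak, ctx)
    merged = base.merge(doubled, on=["tf_from", "tf_to"], suffixes=("_1", "_2"))
    assert np.allclose(merged["score_2"], 2.0 * merged["score_1"])


def test_strong_edges_dominate_weak_nonzero_edges(planted):
    net = planted["bundle"]["network"]
    strong = net.loc[net["strength"] == "strong", "score"]
    weak_nz = net.loc[(net["strength"] == "weak") & (net["score"] > 0), "score"]
    if len(strong) and len(weak_nz):
        assert strong.min() >= weak_nz.max()


def test_all_zero_accessibility_gives_all_zero_weak_edges():
    ctx, expr, motif, peak = _ctx_fixture()
    net = build_interaction_network(["TFA", "TFB"], "leptotene",
                                    expr, motif, peak * 0.0, ctx)
    assert (net["score"] == 0).all()
    assert (net["strength"] == "weak").all()


# ---------------------------------------------------------------------------
# target genes
# ---------------------------------------------------------------------------

def test_motif_with_no_hits_gives_empty_target_set():
    ctx, *_ = _ctx_fixture()
    hm = ctx.hits
    empty = MotifHitMatrix(hits=sp.csr_matrix(np.zeros((4, 1))),
                           scores=sp.csr_matrix(np.zeros((4, 1))),
                           peak_ids=hm.peak_ids, motif_ids=np.array(["MZ"]))
    out = tf_target_genes("TFZ", empty, ctx.pmap, motif_id="MZ")
    assert len(out) == 0


def test_targets_match_brute_force_triple_loop():
    rng = np.random.default_rng(21)
    n_peaks, n_genes = 60, 15
    peak_ids = np.array([f"p{i}" for i in range(n_peaks)])
    h = (rng.random((n_peaks, 1)) < 0.3).astype(float)
    hm = MotifHitMatrix(hits=sp.csr_matrix(h), scores=sp.csr_matrix(h * 5.0),
                        peak_ids=peak_ids, motif_ids=np.array(["M"]))
    pmap = {f"g{j}": sorted(rng.choice(peak_ids,
                                       size=rng.integers(0, 5), replace=False))
            for j in range(n_genes)}
    out = tf_target_genes("TF", hm, pmap, motif_id="M")
    hit_set = {peak_ids[i] for i in np.flatnonzero(h[:, 0])}
    expected = sorted({(g, p) for g, pks in pmap.items()
                       for p in pks if p in hit_set})
    assert sorted(zip(out["gene_id"], out["peak_id"])) == expected


def test_planted_edges_appear_in_target_sets(planted_data):
    from meioscreen import promoter_peak_map as pmap_fn

    ds, hits, genes, truth = (planted_data["ds"], planted_data["hits"],
                              planted_data["genes"], planted_data["truth"])
    pmap = pmap_fn(ds.peak_set, genes, 3000)
    for tf_from, tf_to, pk in truth.planted_edges:
        out = tf_target_genes(tf_from, hits, pmap, motif_id="M" + tf_from[2:])
        assert tf_to in set(out["gene_id"])


# ---------------------------------------------------------------------------
# amplification
# ---------------------------------------------------------------------------

def _expr_fixture():
    # gene 0 pre-expressed, gene 1 switched on at leptotene
    X = np.array([
        [2.0, 0.0],   # mitotic
        [2.0, 0.0],   # transition
        [2.0, 1.0],   # preleptotene
        [4.0, 5.0],   # leptotene
    ])
    cells = pd.DataFrame({"stage": ["mitotic", "transition",
                                    "preleptotene", "leptotene"]})
    return X, cells


def test_threshold_zero_counts_every_gene():
    X, cells = _expr_fixture()
    res = amplification_fraction(X, cells, ["g0", "g1"], ["g0", "g1"],
                                 expr_threshold=0.0)
    assert res.fraction == 1.0


def test_silent_gene_before_meiosis_not_counted():
    X, cells = _expr_fixture()
    res = amplification_fraction(X, cells, ["g1"], ["g0", "g1"])
    assert res.fraction == 0.0
    res2 = amplification_fraction(X, cells, ["g0", "g1"], ["g0", "g1"])
    assert res2.n_pre == 1 and res2.n_up == 2


def test_amplification_monotone_in_threshold():
    rng = np.random.default_rng(8)
    X = rng.uniform(0, 3, size=(40, 25))
    stages = (["mitotic"] * 10 + ["transition"] * 10
              + ["preleptotene"] * 10 + ["leptotene"] * 10)
    cells = pd.DataFrame({"stage": stages})
    ids = [f"g{j}" for j in range(25)]
    prev = 1.1
    for thr in np.linspace(0, 3, 10):
        frac = amplification_fraction(X, cells, ids, ids, expr_threshold=thr,
                                      threshold_mode="absolute").fraction
        assert frac <= prev + 1e-12
        prev = frac


def test_empty_up_genes_rejected():
    X, cells = _expr_fixture()
    with pytest.raises(MultiomeError, match="non-empty"):
        amplification_fraction(X, cells, [], ["g0"])
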