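import numpy as np
import pandas as pd
import pytest
import scipy.sparse as sp

from meioscreen import (
    GeneAnnotation,
    MultiomeDataset,
    PeakSet,
    PipelineConfig,
    SimConfig,
    generate_multiome,
    simulate_and_run,
)

# ---------------------------------------------------------------------------
# fixed study conditions used across the suite
# ---------------------------------------------------------------------------

#: planted conditions: 14 core TFs among 120 candidate motifs, 300 cells
#: per stage, log2 effect 2, 4-fold motif odds in up-DEPs
PLANTED_SEED = 2026

#: no planted signal anywhere: 1,500 cells, 2,000 genes, 5,000 peaks, 40 motifs
NULL_CONFIG = dict(
    n_motifs=40, n_core_tfs=0, n_decoy_tfs=0, n_planted_edges=0,
    frac_de_genes=0.0, frac_de_peaks=0.0, frac_weak_peaks=0.0,
    motif_enrich_odds=1.0, lfc_de_genes=0.0, lfc_core_expr=0.0, seed=909,
)


def small_dataset(n_cells=6, n_genes=4, n_peaks=3, seed=0):
    """Hand-sized paired dataset spanning all five stages."""
    rng = np.random.default_rng(seed)
    stages = ["mitotic", "transition", "preleptotene", "leptotene", "zygotene"]
    cells = pd.DataFrame({
        "cell_id": [f"c{i}" for i in range(n_cells)],
        "stage": [stages[i % 5] for i in range(n_cells)],
    })
    expr = sp.csr_matrix(rng.integers(0, 6, size=(n_cells, n_genes)))
    peaks_mat = sp.csr_matrix(rng.integers(0, 4, size=(n_cells, n_peaks)))
    genes = pd.DataFrame({"gene_id": [f"g{j}" for j in range(n_genes)]})
    peak_set = PeakSet(pd.DataFrame({
        "peak_id": [f"p{j}" for j in range(n_peaks)],
        "chrom": ["chr1"] * n_peaks,
        "start": [100 * j for j in range(n_peaks)],
        "end": [100 * j + 50 for j in range(n_peaks)],
    }))
    return MultiomeDataset(expr=expr, peaks_mat=peaks_mat, cells=cells,
                           genes=genes, peak_set=peak_set).validate()


@pytest.fixture
def tiny_ds():
    return small_dataset()


@pytest.fixture(scope="session")
def planted():
    """Planted dataset at the default study conditions plus the full screen."""
    cfg = SimConfig(seed=PLANTED_SEED)
    bundle, truth = simulate_and_run(cfg)
    return {"config": cfg, "bundle": bundle, "truth": truth}


@pytest.fixture(scope="session")
def planted_data():
    """Raw planted dataset (same conditions as ``planted``)."""
    cfg = SimConfig(seed=PLANTED_SEED)
    ds, hits, genes, truth = generate_multiome(cfg)
    return {"config": cfg, "ds": ds, "hits": hits, "genes": genes,
            "truth": truth}


@pytest.fixture(scope="session")
def null_sim():
    """Dataset with no planted signal at the null-calibration conditions."""
    cfg = SimConfig(**NULL_CONFIG)
    ds, hits, genes, truth = generate_multiome(cfg)
    return {"config": cfg, "ds": ds, "hits": hits, "genes": genes,
            "truth": truth}
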