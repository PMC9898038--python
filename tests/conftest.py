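"""Shared fixtures: a small synthetic cohort (fast, used by unit tests) and the
full default cohort analysis (27 samples x 500 cells, used by the
property-based acceptance checks).  Everything is generated at test time from
fixed seeds."""

from __future__ import annotations

import numpy as np
import pytest

from lscape import malignancy, preprocess, scoring, synthetic

SMALL_SEED = 42
DEFAULT_SEED = 20250923 % (2 ** 31)


@pytest.fixture(scope="session")
def small_cfg():
    return synthetic.default_config(n_genes=1000, cells_per_sample=120, seed=SMALL_SEED)


@pytest.fixture(scope="session")
def small_cohort(small_cfg):
    return synthetic.simulate_cohort(small_cfg)


@pytest.fixture(scope="session")
def small_analysis(small_cfg, small_cohort):
    """QC -> normalize -> reduce -> cluster -> malignancy -> scores -> states."""
    adata, truth = small_cohort
    ad2 = preprocess.qc_filter(adata)
    norm = preprocess.normalize_log(ad2)
    # 800 HVGs: enough to keep the rare QSC population's markers in the
    # dispersion cut so the embedding resolves it from PSP
    emb = preprocess.reduce_and_graph(ad2, norm, n_hvg=800, d=20, k=15, seed=0)
    cr = preprocess.cluster_cells(ad2, emb, resolution=3.0, seed=0)
    mal = malignancy.classify_clusters(cr, ad2.obs)
    scores = scoring.score_cells(ad2, norm, emb.knn_graph, adata.uns["gene_sets"], seed=0)
    assign = scoring.assign_states(scores, mal.per_cell)
    return {"adata": ad2, "truth": truth, "norm": norm, "emb": emb, "cr": cr,
            "mal": mal, "scores": scores, "assign": assign, "cfg": small_cfg}


@pytest.fixture(scope="session")
def default_cohort_analysis():
    """The default-size cohort (2,000 genes, 7 AML + 20 HC samples, 500
    cells/sample) analysed end to end; shared by the acceptance checks."""
    cfg = synthetic.default_config(seed=DEFAULT_SEED)
    adata, truth = synthetic.simulate_cohort(cfg)
    ad2 = preprocess.qc_filter(adata)
    norm = preprocess.normalize_log(ad2)
    emb = preprocess.reduce_and_graph(ad2, norm, n_hvg=1000, d=30, k=15, seed=0)
    cr = preprocess.cluster_cells(ad2, emb, resolution=3.0, seed=0)
    mal = malignancy.classify_clusters(cr, ad2.obs)
    scores = scoring.score_cells(ad2, norm, emb.knn_graph, adata.uns["gene_sets"], seed=0)
    assign = scoring.assign_states(scores, mal.per_cell)
    return {"adata": ad2, "truth": truth, "norm": norm, "emb": emb, "cr": cr,
            "mal": mal, "scores": scores, "assign": assign, "cfg": cfg}


STATE_POTENCY = {"QSC": 3, "PSP": 3, "GMP": 2, "PG": 2, "promono": 1, "mono": 0}


def leukemia_truth_mask(analysis):
    """True-state series of assigned leukemia-like cells plus leukemia mask."""
    ts = analysis["adata"].obs["true_state"].loc[analysis["assign"].states.index]
    return ts, ts.isin(synthetic.LEUKEMIA_STATES)
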