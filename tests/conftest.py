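"""Shared fixtures: a default synthetic panel run through the full pipeline."""
from __future__ import annotations

import collections

import numpy as np
import pytest
from hypothesis import settings

import chemopath as cp

settings.register_profile("deterministic", derandomize=True, deadline=None)
settings.load_profile("deterministic")

BUNDLE_SEED = 11


@pytest.fixture(scope="session")
def bundle():
    """Default synthetic panel with ground truth."""
    expr, chemo, pw, truth = cp.generate_panel(seed=BUNDLE_SEED)
    return {"expr": expr, "chemo": chemo, "pathways": pw, "truth": truth}


@pytest.fixture(scope="session")
def pipe(bundle):
    """The panel taken through normalize -> SOM -> correlations -> H-scores."""
    cfg = cp.RunConfig(rng_seed=BUNDLE_SEED)
    norm, expr_f, pw_f, report = cp.normalize_pipeline(
        bundle["chemo"], bundle["expr"], bundle["pathways"], cfg
    )
    model = cp.train_som(norm, cfg, rows=3, cols=3, seed=BUNDLE_SEED)
    asn = cp.assign_all(model, norm)
    truth = bundle["truth"]
    counts = {c: collections.Counter() for c in truth.clusters}
    for comp, node in asn.node.items():
        counts[truth.compound_cluster[comp]][node] += 1
    cluster_node = {c: counts[c].most_common(1)[0][0] for c in truth.clusters}
    corr = cp.gene_node_correlations(expr_f, model)
    table = cp.h_score_table(corr, pw_f)
    return {
        "config": cfg,
        "norm": norm,
        "expr_f": expr_f,
        "pw_f": pw_f,
        "report": report,
        "model": model,
        "assignments": asn,
        "cluster_node": cluster_node,
        "corr": corr,
        "table": table,
    }


@pytest.fixture(scope="session")
def converged_dset(bundle, pipe):
    """A converged DiscriminantSet for cluster 0's node."""
    node = pipe["cluster_node"][0]
    profile = cp.codebook_profile(pipe["model"], node)
    pool = cp.candidate_pool(node, pipe["table"], pipe["expr_f"], profile,
                             pipe["pw_f"], pipe["config"])
    dset = cp.trim(pool, pipe["expr_f"], profile, pipe["config"], node=node)
    assert dset.converged
    return dset


def block_design(n_genes=10, n_cells=20, gap=4.0, seed=0):
    """Perfect four-class block design: over-genes high exactly in sensitive cells.

    Returns (expr, profile, pool_frame) with the first half of the genes
    negatively and the second half positively associated with sensitivity.
    """
    import pandas as pd

    rng = np.random.default_rng(seed)
    cells = tuple(f"C{i:02d}" for i in range(n_cells))
    panel = cp.CellPanel(cells)
    half_cells = n_cells // 2
    profile = np.array([-1.0] * half_cells + [1.0] * (n_cells - half_cells))
    X = 0.05 * rng.standard_normal((n_genes, n_cells))
    half_genes = n_genes // 2
    X[:half_genes, :half_cells] += gap  # over-expressed in insensitive cells
    X[half_genes:, half_cells:] += gap  # over-expressed in sensitive cells
    genes = [f"g{i}" for i in range(n_genes)]
    expr = cp.ExpressionMatrix(pd.DataFrame(X, index=genes, columns=cells), panel)
    r = np.array([-0.9] * half_genes + [0.9] * (n_genes - half_genes))
    pool = pd.DataFrame({"gene": genes, "r": r, "p": 1e-6})
    return expr, profile, pool
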