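"""Overlap-style gene-set enrichment via the hypergeometric upper tail.

Given a query list of discriminating genes and a gene-set collection, each
set is scored by the probability of observing at least the seen overlap when
drawing the query at random from the universe of measured genes. Only sets
sharing at least ``min_overlap`` genes with the query are reported;
Benjamini-Hochberg adjusted p-values accompany the raw ones, but ranking
follows the raw p.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .config import RunConfig
from .data import PathwayCollection

log = logging.getLogger(__name__)

__all__ = ["EnrichmentRecord", "hypergeometric_tail", "enrichment_report"]


@dataclass
class EnrichmentRecord:
    name: str
    description: str
    k: int  # overlap
    K: int  # set size within universe
    n: int  # query size
    N: int  # universe size
    p_value: float
    p_adjusted: float
    genes: list[str]


def hypergeometric_tail(k: int, K: int, n: int, N: int) -> float:
    """P(X >= k) for X ~ Hypergeometric(N, K, n).

    N is the universe size, K the set size, n the query size, k the overlap.
    """
    if not (0 <= k <= min(K, n) <= N) or K > N or n > N:
        raise ValueError(f"inconsistent counts: k={k}, K={K}, n={n}, N={N}")
    if k == 0:
        return 1.0
    return float(stats.hypergeom.sf(k - 1, N, K, n))


def enrichment_report(
    query_genes,
    collection: PathwayCollection,
    universe,
    config: RunConfig | None = None,
    top_k: int | None = None,
) -> list[EnrichmentRecord]:
    """Hypergeometric over-representation of the query in each gene set.

    The universe is the set of genes that survived expression filtering;
    query genes outside it are logged and dropped. Sets are conditioned on
    the universe (K counts only measured members). Records with overlap
    k >= min_overlap are returned sorted by raw p ascending (name on ties);
    BH adjustment is computed across all sets tested (every set with at
    least one measured member).
    """
    config = config or RunConfig()
    universe = set(universe)
    if not universe:
        raise ValueError("empty gene universe")
    query = set(query_genes)
    outside = query - universe
    if outside:
        log.warning("enrichment_report: %d query genes outside universe dropped", len(outside))
        query &= universe
    N = len(universe)
    n = len(query)

    tested: list[tuple] = []
    for pw in collection:
        members = pw.genes & universe
        K = len(members)
        if K == 0:
            continue
        overlap = sorted(members & query)
        k = len(overlap)
        p = hypergeometric_tail(k, K, n, N)
        tested.append((pw.name, pw.description, k, K, p, overlap))
    if not tested:
        return []
    pvals = np.array([t[4] for t in tested])
    _, p_adj, _, _ = multipletests(pvals, method="fdr_bh")

    records = [
        EnrichmentRecord(name, desc, k, K, n, N, float(p), float(pa), overlap)
        for (name, desc, k, K, p, overlap), pa in zip(tested, p_adj)
        if k >= config.min_overlap
    ]
    records.sort(key=lambda r: (r.p_value, r.name))
    if top_k is not None:
        records = records[:top_k]
    return records


def report_frame(records: list[EnrichmentRecord]) -> pd.DataFrame:
    """Table-shaped view: name, description, overlap, p, adjusted p, genes."""
    return pd.DataFrame(
        [
            {
                "name": r.name,
                "description": r.description,
                "overlap": r.k,
                "set_size": r.K,
                "p": r.p_value,
                "p_adjusted": r.p_adjusted,
                "genes": ",".join(r.genes),
            }
            for r in records
        ],
        columns=["name", "description", "overlap", "set_size", "p", "p_adjusted", "genes"],
    )
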