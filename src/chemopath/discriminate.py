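"""Discriminating-gene selection: candidate pool and iterative t-test trimming.

Starting from the genes of the top-decile H-score pathways at a node, the
pool is restricted to genes significantly correlated with the node's
chemoactivity profile. The pool is then trimmed by a two-step iterative
Student's t-test: (1) per gene, expression must differ between the current
chemo-sensitive and chemo-insensitive cells; (2) per cell, the expression of
the over-associated gene group must differ from the under-associated group.
Iteration stops when every remaining gene and cell is separable in its
dimension, yielding four classes: over-expressed/insensitive (A),
under-expressed/sensitive (B), under-expressed/insensitive (C) and
over-expressed/sensitive (D).
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ._stats import corr_pvalues, masked_corr_matrix, two_sample_t_rows
from .config import RunConfig
from .data import ExpressionMatrix, PathwayCollection
from .hscore import HScoreTable, top_percentile_pathways

log = logging.getLogger(__name__)

__all__ = [
    "DiscriminantSet",
    "candidate_pool",
    "trim",
    "four_class_labels",
    "shuffle_null_fpr",
]


@dataclass
class DiscriminantSet:
    """Converged (or failed) result of the iterative trimming procedure.

    Genes are ordered by their initial correlation with the chemoactivity
    profile, most negative first; cells are ordered by chemoactivity value,
    most insensitive (negative) first. ``gene_class`` is "over_insensitive"
    for negatively correlated genes and "over_sensitive" for positively
    correlated ones; ``cell_class`` is "sensitive" (chemoactivity > 0) or
    "insensitive".
    """

    node: object
    genes: list[str]
    gene_r: dict[str, float]
    gene_class: dict[str, str]
    cells: list[str]
    cell_class: dict[str, str]
    gene_p: dict[str, float]
    cell_p: dict[str, float]
    n_iterations: int
    converged: bool
    failure: str | None = None
    n_genes_input: int = 0
    n_cells_input: int = 0

    @property
    def n_genes(self) -> int:
        return len(self.genes)

    @property
    def n_cells(self) -> int:
        return len(self.cells)

    def to_dict(self) -> dict:
        return {
            "node": self.node,
            "genes": self.genes,
            "gene_r": self.gene_r,
            "gene_class": self.gene_class,
            "cells": self.cells,
            "cell_class": self.cell_class,
            "gene_p": self.gene_p,
            "cell_p": self.cell_p,
            "n_iterations": self.n_iterations,
            "converged": self.converged,
            "failure": self.failure,
            "n_genes_input": self.n_genes_input,
            "n_cells_input": self.n_cells_input,
        }


def candidate_pool(
    node,
    hscore_table: HScoreTable,
    expr: ExpressionMatrix,
    chemo_profile: np.ndarray,
    pathways: PathwayCollection,
    config: RunConfig | None = None,
) -> pd.DataFrame:
    """Genes of the top-decile pathways significantly correlated with the profile.

    Returns a DataFrame with columns gene, r, p, ordered by r ascending
    (most negative first); empty if nothing qualifies (flagged by emptiness,
    not an error). The profile may be a SOM codebook vector or a raw
    compound profile over the same panel.
    """
    config = config or RunConfig()
    top = top_percentile_pathways(hscore_table, node, config.h_top_percentile)
    members: set[str] = set()
    for name in top:
        members |= pathways[name].genes
    genes = [g for g in expr.gene_ids if g in members]
    if not genes:
        return pd.DataFrame(columns=["gene", "r", "p"])
    sub = expr.subset(genes)
    R, N = masked_corr_matrix(sub.values(), np.asarray(chemo_profile, dtype=float)[None, :])
    p = corr_pvalues(R, N)[:, 0]
    r = R[:, 0]
    keep = np.isfinite(p) & (p < config.corr_alpha)
    out = pd.DataFrame({"gene": np.array(genes)[keep], "r": r[keep], "p": p[keep]})
    return out.sort_values("r", kind="mergesort").reset_index(drop=True)


def _trim_arrays(
    X: np.ndarray,
    gene_neg: np.ndarray,
    cell_sens: np.ndarray,
    alpha: float,
    max_iter: int,
    equal_var: bool = True,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray, int, bool, str | None]:
    """Core iterative trim on plain arrays.

    X: (genes, cells) expression; gene_neg: True where the gene's initial
    correlation is negative (over-with-insensitive class); cell_sens: True
    for chemo-sensitive cells. Returns (gene_keep, cell_keep, gene_p,
    cell_p, n_iter, converged, failure).
    """
    n_genes, n_cells = X.shape
    gkeep = np.ones(n_genes, dtype=bool)
    ckeep = np.ones(n_cells, dtype=bool)
    gene_p = np.full(n_genes, np.nan)
    cell_p = np.full(n_cells, np.nan)
    failure = None
    converged = False
    it = 0
    while it < max_iter:
        it += 1
        dropped = False

        sens = ckeep & cell_sens
        insens = ckeep & ~cell_sens
        if sens.sum() < 2 or insens.sum() < 2:
            failure = "cell class emptied (degenerate t-test)"
            break
        gi = np.where(gkeep)[0]
        _, p = two_sample_t_rows(X[np.ix_(gi, np.where(sens)[0])],
                                 X[np.ix_(gi, np.where(insens)[0])],
                                 equal_var=equal_var)
        gene_p[gi] = p
        pass_g = np.isfinite(p) & (p < alpha)
        if not pass_g.all():
            dropped = True
        gkeep[gi] = pass_g
        over = gkeep & gene_neg
        under = gkeep & ~gene_neg
        if over.sum() < 2 or under.sum() < 2:
            failure = (
                "gene class emptied: "
                + ("over_insensitive" if over.sum() < 2 else "over_sensitive")
            )
            break

        ci = np.where(ckeep)[0]
        # per cell: over-group vs under-group gene expression (transpose view)
        _, p = two_sample_t_rows(X[np.ix_(np.where(over)[0], ci)].T,
                                 X[np.ix_(np.where(under)[0], ci)].T,
                                 equal_var=equal_var)
        cell_p[ci] = p
        pass_c = np.isfinite(p) & (p < alpha)
        if not pass_c.all():
            dropped = True
        ckeep[ci] = pass_c
        if (ckeep & cell_sens).sum() < 2 or (ckeep & ~cell_sens).sum() < 2:
            failure = (
                "cell class emptied: "
                + ("sensitive" if (ckeep & cell_sens).sum() < 2 else "insensitive")
            )
            break

        if not dropped:
            converged = True
            break
    else:
        failure = "no convergence at max_iter"
    return gkeep, ckeep, gene_p, cell_p, it, converged, failure


def trim(
    pool: pd.DataFrame,
    expr: ExpressionMatrix,
    chemo_profile: np.ndarray,
    config: RunConfig | None = None,
    node=None,
) -> DiscriminantSet:
    """Iterative two-step Student's t-test trimming of the candidate pool.

    Cells start split by the sign of the chemoactivity profile (positive =
    sensitive; exactly 0 counts as insensitive); only cells with an observed
    chemoactivity participate. Gene over/under classes are fixed once from
    the sign of each gene's initial correlation and not recomputed.
    """
    config = config or RunConfig()
    if pool.empty:
        raise ValueError("cannot trim an empty candidate pool")
    profile = np.asarray(chemo_profile, dtype=float)
    cell_obs = np.isfinite(profile)
    cells = [c for c, ok in zip(expr.panel.cell_ids, cell_obs) if ok]
    genes = list(pool["gene"])
    gene_r = dict(zip(pool["gene"], pool["r"]))
    sub = expr.subset(genes)
    genes = sub.gene_ids  # preserves expr order of pool genes
    X = sub.data.loc[:, cells].to_numpy()
    gene_neg = np.array([gene_r[g] < 0 for g in genes])
    chemo = profile[cell_obs]
    cell_sens = chemo > 0

    gkeep, ckeep, gene_p, cell_p, it, converged, failure = _trim_arrays(
        X, gene_neg, cell_sens, config.trim_alpha, config.max_iter,
        equal_var=config.equal_var_t,
    )

    kept_genes = [g for g, k in zip(genes, gkeep) if k] if failure is None else []
    kept_cells = [c for c, k in zip(cells, ckeep) if k] if failure is None else []
    # final ordering: genes by initial r ascending; cells by chemoactivity ascending
    kept_genes.sort(key=lambda g: (gene_r[g], g))
    cell_val = dict(zip(cells, chemo))
    kept_cells.sort(key=lambda c: (cell_val[c], c))
    gidx = {g: i for i, g in enumerate(genes)}
    cidx = {c: i for i, c in enumerate(cells)}
    return DiscriminantSet(
        node=node,
        genes=kept_genes,
        gene_r={g: float(gene_r[g]) for g in kept_genes},
        gene_class={
            g: ("over_insensitive" if gene_r[g] < 0 else "over_sensitive")
            for g in kept_genes
        },
        cells=kept_cells,
        cell_class={c: ("sensitive" if cell_val[c] > 0 else "insensitive") for c in kept_cells},
        gene_p={g: float(gene_p[gidx[g]]) for g in kept_genes},
        cell_p={c: float(cell_p[cidx[c]]) for c in kept_cells},
        n_iterations=it,
        converged=converged,
        failure=failure,
        n_genes_input=len(genes),
        n_cells_input=len(cells),
    )


def four_class_labels(dset: DiscriminantSet) -> pd.DataFrame:
    """Per-(gene, cell) quadrant labels A-D.

    A: negatively correlated genes x insensitive cells (over/insensitive),
    B: negative x sensitive, C: positive x insensitive, D: positive x
    sensitive. Every pair lands in exactly one quadrant.
    """
    if not dset.converged:
        raise ValueError("four_class_labels requires a converged DiscriminantSet")
    labels = np.empty((dset.n_genes, dset.n_cells), dtype="<U1")
    for i, g in enumerate(dset.genes):
        neg = dset.gene_class[g] == "over_insensitive"
        for j, c in enumerate(dset.cells):
            sens = dset.cell_class[c] == "sensitive"
            labels[i, j] = ("B" if sens else "A") if neg else ("D" if sens else "C")
    return pd.DataFrame(labels, index=dset.genes, columns=dset.cells)


def shuffle_null_fpr(
    dset: DiscriminantSet,
    expr: ExpressionMatrix,
    config: RunConfig | None = None,
    n_perm: int = 10_000,
    seed: int = 0,
) -> float:
    """Permutation estimate of the false-positive rate of the trimming tests.

    For each permutation round, every discriminating gene's expression values
    are independently shuffled across the retained cells and the full
    two-step iterative trim is re-applied from the original class labels.
    The returned estimate is the fraction of shuffled genes that survive to
    a converged set; with real structure destroyed this is typically orders
    of magnitude below the nominal per-test threshold.
    """
    config = config or RunConfig()
    if n_perm < 100:
        raise ValueError("n_perm < 100 yields a meaningless estimate")
    if not dset.converged or not dset.genes:
        raise ValueError("shuffle_null_fpr requires a converged, non-empty DiscriminantSet")
    sub = expr.subset(dset.genes)
    X = sub.data.loc[dset.genes, dset.cells].to_numpy()
    gene_neg = np.array([dset.gene_class[g] == "over_insensitive" for g in dset.genes])
    cell_sens = np.array([dset.cell_class[c] == "sensitive" for c in dset.cells])
    rng = np.random.default_rng(seed)
    n_genes = len(dset.genes)
    survivors = 0
    for _ in range(n_perm):
        Xp = rng.permuted(X, axis=1)
        gkeep, _, _, _, _, converged, failure = _trim_arrays(
            Xp, gene_neg, cell_sens, config.trim_alpha, config.max_iter,
            equal_var=config.equal_var_t,
        )
        if failure is None and converged:
            survivors += int(gkeep.sum())
    return survivors / (n_perm * n_genes)
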