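"""Synthetic NCI60-like panel generator with full ground truth.

Emulates the structure the mining pipeline consumes: a ~59-line tumor cell
panel; compound clusters whose members share a base chemoactivity profile
plus replicate noise; pathway-coherent expression blocks in which planted
genes shift between the chemo-sensitive and chemo-insensitive cells of
their cluster; and background genes that are pure noise.

Planted pathways have a dominant direction: most members are up in
sensitive cells (positive correlation with chemoactivity) while a minority
are up in insensitive cells, the way a coordinated pathway still carries
suppressor-like genes. The dominant tilt is what gives the pathway a large
positive rank-sum H-score at its cluster's node (a 50/50 mix would center
the members' mean rank and null the statistic), while the minority
populates the under-expressed discriminant classes, so all four classes
A-D exist by construction. Everything is deterministic for a fixed seed.

The generator does not attempt to mimic real NCI60 tissue-of-origin
correlation structure or dose-response shapes; see the methods note for
what that implies about test coverage.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .data import (
    CellPanel,
    ChemoProfileSet,
    ExpressionMatrix,
    Pathway,
    PathwayCollection,
)

log = logging.getLogger(__name__)

__all__ = ["SyntheticTruth", "generate_panel", "degrade"]

_TISSUES = (
    "breast", "cns", "colon", "leukemia", "melanoma",
    "nsclc", "ovarian", "prostate", "renal",
)


@dataclass
class SyntheticTruth:
    """Ground truth emitted alongside a synthetic panel."""

    planted_pathways: dict[int, str]
    planted_genes: dict[int, list[str]]
    sensitive_cells: dict[int, list[str]]
    base_profiles: dict[int, list[float]]
    gene_effect: dict[str, float]  # signed between-class mean shift
    compound_cluster: dict[str, int]
    noise_sd: float
    effect_size: float
    seed: int
    clusters: list[int] = field(default_factory=list)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "planted_pathways": {str(k): v for k, v in self.planted_pathways.items()},
            "planted_genes": {str(k): v for k, v in self.planted_genes.items()},
            "sensitive_cells": {str(k): v for k, v in self.sensitive_cells.items()},
            "base_profiles": {str(k): v for k, v in self.base_profiles.items()},
            "gene_effect": self.gene_effect,
            "compound_cluster": self.compound_cluster,
            "noise_sd": self.noise_sd,
            "effect_size": self.effect_size,
            "seed": self.seed,
            "clusters": self.clusters,
        }
        Path(path).write_text(json.dumps(payload))


def generate_panel(
    n_cells: int = 59,
    n_genes: int = 600,
    n_pathways: int = 40,
    pathway_size_range: tuple[int, int] = (8, 25),
    n_clusters: int = 4,
    compounds_per_cluster: int = 10,
    effect_size: float = 1.5,
    noise_sd: float = 0.5,
    missing_rate: float = 0.05,
    seed: int = 0,
) -> tuple[ExpressionMatrix, ChemoProfileSet, PathwayCollection, SyntheticTruth]:
    """Generate an aligned (expression, chemoactivity, pathways, truth) bundle.

    Per cluster: a sensitive-cell subset is drawn (both classes >= 5 cells);
    the base chemoactivity profile is +1 on sensitive and -1 on insensitive
    cells, and each member compound adds N(0, noise_sd) replicate noise
    (masked at ``missing_rate``). One planted pathway per cluster carries
    genes whose expression is shifted by ``effect_size`` between classes
    (residual expression noise sd = ``noise_sd``); roughly three quarters
    shift up in sensitive cells, and at least two members shift the other
    way. All other genes are i.i.d. N(0, 1) background.
    """
    lo, hi = pathway_size_range
    if lo < 2:
        raise ValueError("pathway sizes must be >= 2")
    if n_pathways < n_clusters:
        raise ValueError("need at least one pathway per compound cluster")
    if n_cells < 12:
        raise ValueError("panel too small for non-trivial sensitivity splits")
    rng = np.random.default_rng(seed)

    cells = tuple(f"CL{i + 1:02d}" for i in range(n_cells))
    tissue = tuple(_TISSUES[i % len(_TISSUES)] for i in range(n_cells))
    panel = CellPanel(cells, tissue)
    genes = [f"G{i + 1:04d}" for i in range(n_genes)]

    # planted pathway sizes and dedicated gene blocks
    planted_sizes = rng.integers(lo, hi + 1, size=n_clusters)
    if planted_sizes.sum() > n_genes:
        raise ValueError("not enough genes for the planted pathways")
    planted_genes: dict[int, list[str]] = {}
    cursor = 0
    for c in range(n_clusters):
        size = int(planted_sizes[c])
        planted_genes[c] = genes[cursor : cursor + size]
        cursor += size
    background = genes[cursor:]
    if len(background) < hi:
        raise ValueError("not enough background genes for decoy pathways")

    # sensitivity splits: each cell is sensitive in exactly half the clusters
    # (balanced design -> no cell-line has a net sensitivity bias, matching
    # the assumption behind the across-cell normalization stage)
    min_side = 5
    per_cell = max(1, n_clusters // 2)
    for _ in range(100):
        masks = np.zeros((n_clusters, n_cells), dtype=bool)
        for j in range(n_cells):
            chosen = rng.choice(n_clusters, size=per_cell, replace=False)
            masks[chosen, j] = True
        counts = masks.sum(axis=1)
        if np.all(counts >= min_side) and np.all(n_cells - counts >= min_side):
            break
    else:
        raise ValueError("could not draw non-trivial sensitivity splits")

    sensitive: dict[int, list[str]] = {}
    base: dict[int, np.ndarray] = {}
    comp_rows: list[np.ndarray] = []
    comp_ids: list[str] = []
    comp_cluster: dict[str, int] = {}
    for c in range(n_clusters):
        mask = masks[c]
        sensitive[c] = [cells[i] for i in range(n_cells) if mask[i]]
        s = np.where(mask, 1.0, -1.0)
        base[c] = s
        for j in range(compounds_per_cluster):
            cid = f"CMP-{c + 1}-{j + 1:02d}"
            y = s + noise_sd * rng.standard_normal(n_cells)
            if missing_rate > 0:
                miss = rng.random(n_cells) < missing_rate
                y = np.where(miss, np.nan, y)
            comp_rows.append(y)
            comp_ids.append(cid)
            comp_cluster[cid] = c
    chemo = ChemoProfileSet(
        pd.DataFrame(np.vstack(comp_rows), index=comp_ids, columns=cells), panel
    )

    # expression: background noise, then planted blocks
    X = rng.standard_normal((n_genes, n_cells))
    gene_effect: dict[str, float] = {}
    gene_pos = {g: i for i, g in enumerate(genes)}
    for c in range(n_clusters):
        s = base[c]
        n_minority = max(2, len(planted_genes[c]) // 4)
        for rank, g in enumerate(planted_genes[c]):
            direction = -1.0 if rank < n_minority else 1.0
            shift = direction * effect_size
            X[gene_pos[g]] = shift / 2.0 * s + noise_sd * rng.standard_normal(n_cells)
            gene_effect[g] = shift
    expr = ExpressionMatrix(pd.DataFrame(X, index=genes, columns=cells), panel)

    # pathways: one planted per cluster plus background decoys
    pathways: list[Pathway] = []
    planted_names: dict[int, str] = {}
    sources = ("KEGG", "BIOCARTA", "GO")
    for c in range(n_clusters):
        name = f"PW{c + 1:03d}"
        planted_names[c] = name
        pathways.append(
            Pathway(name, f"synthetic planted pathway, cluster {c + 1}",
                    frozenset(planted_genes[c]), sources[c % 3])
        )
    for i in range(n_clusters, n_pathways):
        size = int(rng.integers(lo, hi + 1))
        members = rng.choice(background, size=size, replace=False)
        pathways.append(
            Pathway(f"PW{i + 1:03d}", "synthetic background pathway",
                    frozenset(members.tolist()), sources[i % 3])
        )
    collection = PathwayCollection.from_pathways(pathways)

    truth = SyntheticTruth(
        planted_pathways=planted_names,
        planted_genes=planted_genes,
        sensitive_cells=sensitive,
        base_profiles={c: base[c].tolist() for c in base},
        gene_effect=gene_effect,
        compound_cluster=comp_cluster,
        noise_sd=noise_sd,
        effect_size=effect_size,
        seed=seed,
        clusters=list(range(n_clusters)),
    )
    return expr, chemo, collection, truth


def degrade(expr: ExpressionMatrix, sigma: float, seed: int = 0) -> ExpressionMatrix:
    """Add i.i.d. N(0, sigma^2) white noise to observed expression values.

    Masked entries stay masked; sigma = 0 returns an identical matrix.
    """
    if sigma < 0:
        raise ValueError("sigma must be >= 0")
    vals = expr.values().copy()
    if sigma > 0:
        rng = np.random.default_rng(seed)
        noise = rng.standard_normal(vals.shape) * sigma
        obs = np.isfinite(vals)
        vals[obs] = vals[obs] + noise[obs]
    return ExpressionMatrix(
        pd.DataFrame(vals, index=expr.data.index, columns=expr.data.columns), expr.panel
    )
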