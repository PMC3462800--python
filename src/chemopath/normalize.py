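"""Profile filtering and two-stage GI50 normalization; gene/pathway filters.

Chemoactivity filtering keeps only profiles reported on more than a minimum
number of cell lines (default 40 of ~59) and with enough differential
response (coefficient of variation >= 0.05) to be informative; near-flat
profiles reflect compound inactivity or pan-cytotoxicity, not selectivity.

Normalization is two-stage: first across tumor cell lines (per cell-line
column) to remove systematic per-cell sensitivity biases, then within each
compound record to a z-score, so that positive values mark chemo-sensitive
cells and negative values chemo-insensitive ones.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .config import RunConfig
from .data import ChemoProfileSet, ExpressionMatrix, Pathway, PathwayCollection

log = logging.getLogger(__name__)

__all__ = [
    "FilterReport",
    "filter_chemo_profiles",
    "normalize_chemo",
    "filter_expression_genes",
    "filter_pathways",
]

_MEAN_FLOOR = 1e-12


@dataclass
class FilterReport:
    n_input: int
    n_kept: int
    n_dropped_min_cells: int
    n_dropped_cv: int

    def __post_init__(self) -> None:
        assert self.n_input == self.n_kept + self.n_dropped_min_cells + self.n_dropped_cv

    def to_dict(self) -> dict:
        return self.__dict__.copy()


def _cv(values: np.ndarray) -> float:
    """Coefficient of variation sd/|mean| over observed entries.

    |mean| is floored at 1e-12; profiles centered at ~0 (where CV is
    pathological) are scored by their sd alone.
    """
    obs = values[np.isfinite(values)]
    if len(obs) < 2:
        return 0.0
    sd = float(np.std(obs, ddof=1))
    mean = abs(float(np.mean(obs)))
    if mean < _MEAN_FLOOR:
        return sd
    return sd / mean


def filter_chemo_profiles(
    chemo: ChemoProfileSet, min_cells: int = 40, min_cv: float = 0.05
) -> tuple[ChemoProfileSet, FilterReport]:
    """Keep profiles with > min_cells reported values and CV >= min_cv.

    The cell-count rule is strict ("more than"): a profile observed on
    exactly ``min_cells`` lines is dropped. Input row order is preserved.
    """
    if chemo.normalized:
        raise ValueError("filter_chemo_profiles expects raw (un-normalized) profiles")
    vals = chemo.values()
    n_obs = np.isfinite(vals).sum(axis=1)
    keep_cells = n_obs > min_cells
    # fewer than 2 observed values: CV undefined, counted as a cell-count drop
    keep_cells &= n_obs >= 2
    cvs = np.array([_cv(row) for row in vals])
    keep = keep_cells & (cvs >= min_cv)
    report = FilterReport(
        n_input=chemo.n_compounds,
        n_kept=int(keep.sum()),
        n_dropped_min_cells=int((~keep_cells).sum()),
        n_dropped_cv=int((keep_cells & (cvs < min_cv)).sum()),
    )
    kept = ChemoProfileSet(chemo.data.loc[keep], chemo.panel, normalized=False)
    return kept, report


def normalize_chemo(chemo: ChemoProfileSet, stage1_mode: str = "zscore") -> ChemoProfileSet:
    """Two-stage normalization to per-compound GI50 z-scores.

    Stage 1 standardizes each cell-line column over all compounds (subtract
    the column mean and, in ``zscore`` mode, divide by the column sd;
    ``center`` mode subtracts the mean only). Columns with zero variance are
    centered only, with a warning. Stage 2 z-scores each compound row over
    its observed cells. A set already flagged normalized is returned
    unchanged, making the operation idempotent.
    """
    if chemo.normalized:
        log.info("normalize_chemo: input already normalized; returning unchanged")
        return chemo
    vals = chemo.values().copy()

    if chemo.n_compounds < 2:
        # cell-line bias is not estimable from a single record; stage 2 only
        log.warning("normalize_chemo: single profile, skipping stage-1 normalization")
    else:
        col_mean = np.nanmean(vals, axis=0)
        vals = vals - col_mean
    if chemo.n_compounds >= 2 and stage1_mode == "zscore":
        col_sd = np.nanstd(vals, axis=0, ddof=1)
        flat = ~np.isfinite(col_sd) | (col_sd <= 0)
        if flat.any():
            log.warning(
                "stage-1: %d cell line(s) with zero variance; centered only", int(flat.sum())
            )
        scale = np.where(flat, 1.0, col_sd)
        vals = vals / scale

    row_mean = np.nanmean(vals, axis=1, keepdims=True)
    row_sd = np.nanstd(vals, axis=1, ddof=1, keepdims=True)
    bad = ~np.isfinite(row_sd) | (row_sd <= 0)
    if bad.any():
        log.warning("stage-2: %d constant profile(s) centered only", int(bad.sum()))
    vals = (vals - row_mean) / np.where(bad, 1.0, row_sd)

    out = pd.DataFrame(vals, index=chemo.data.index, columns=chemo.data.columns)
    return ChemoProfileSet(out, chemo.panel, normalized=True)


def filter_expression_genes(
    expr: ExpressionMatrix, pathways: PathwayCollection, min_cv: float = 0.05
) -> ExpressionMatrix:
    """Keep genes with CV > min_cv that share a pathway with another measured gene.

    A gene absent from every pathway is dropped regardless of variation; a
    pathway containing only one measured gene rescues nobody ("sharing at
    least one *other* gene"). Gene symbol matching is exact and
    case-sensitive. Input row order is preserved.
    """
    vals = expr.values()
    cvs = np.array([_cv(row) for row in vals])
    measured = set(expr.gene_ids)
    companions: set[str] = set()
    for pw in pathways:
        present = pw.genes & measured
        if len(present) >= 2:
            companions |= present
    keep = [
        (cv > min_cv) and (g in companions) for g, cv in zip(expr.gene_ids, cvs)
    ]
    kept = expr.data.loc[keep]
    if kept.empty:
        log.warning("filter_expression_genes: no genes passed the filters")
    return ExpressionMatrix(kept, expr.panel) if len(kept) else _empty_like(expr)


def _empty_like(expr: ExpressionMatrix) -> ExpressionMatrix:
    obj = ExpressionMatrix.__new__(ExpressionMatrix)
    obj.data = expr.data.iloc[0:0]
    obj.panel = expr.panel
    return obj


def filter_pathways(
    pathways: PathwayCollection, expr: ExpressionMatrix, min_present: int = 2
) -> PathwayCollection:
    """Keep pathways with at least ``min_present`` genes in the expression set."""
    measured = set(expr.gene_ids)
    kept = [pw for pw in pathways if len(pw.genes & measured) >= min_present]
    return PathwayCollection.from_pathways(kept)


def normalize_pipeline(
    chemo: ChemoProfileSet,
    expr: ExpressionMatrix,
    pathways: PathwayCollection,
    config: RunConfig,
) -> tuple[ChemoProfileSet, ExpressionMatrix, PathwayCollection, FilterReport]:
    """Convenience: full filtering + normalization stage in prescribed order."""
    kept, report = filter_chemo_profiles(chemo, config.min_cells_reported, config.min_cv)
    norm = normalize_chemo(kept, stage1_mode=config.stage1_mode)
    expr_f = filter_expression_genes(expr, pathways, config.min_cv)
    pw_f = filter_pathways(pathways, expr_f, config.min_pathway_genes)
    return norm, expr_f, pw_f, report
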