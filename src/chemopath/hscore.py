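"""Signed Kruskal-Wallis pathway H-scores against SOM chemoactivity profiles.

For each reference chemoactivity profile (a SOM codebook vector, or a raw
compound profile), every gene's expression is correlated with the profile
across the cell panel. For each pathway, the jointly ranked correlations of
member vs non-member genes are compared with a Kruskal-Wallis rank-sum
statistic H: a large H means the pathway's genes sit non-randomly in the
correlation ranking, i.e. the pathway is coherently associated (positively
or negatively) with the chemoactivity. The score is given the sign of
(mean member correlation - mean non-member correlation); p-values come from
the chi-square approximation with 1 df (two groups) on the unsigned H.
"""
from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from ._stats import masked_corr_matrix, masked_pearson
from .data import ExpressionMatrix, PathwayCollection
from .som import SOMModel

log = logging.getLogger(__name__)

__all__ = [
    "CorrelationMatrix",
    "HScoreRecord",
    "HScoreTable",
    "pearson_masked",
    "gene_node_correlations",
    "gene_profile_correlations",
    "kruskal_wallis",
    "pathway_h",
    "h_score_table",
    "top_percentile_pathways",
]


@dataclass
class CorrelationMatrix:
    """Pearson r between every gene and every reference profile.

    ``r`` and ``n_used`` are (genes x profiles) DataFrames; undefined entries
    (overlap < 3 cells or zero variance) are NaN in ``r``.
    """

    r: pd.DataFrame
    n_used: pd.DataFrame

    @property
    def gene_ids(self) -> list[str]:
        return list(self.r.index)

    @property
    def profile_labels(self) -> list:
        return list(self.r.columns)


@dataclass
class HScoreRecord:
    pathway: str
    node: object
    H: float  # signed
    p_value: float
    n_in: int
    n_out: int
    mean_r_in: float
    mean_r_out: float
    valid: bool = True


class HScoreTable:
    """One signed-H record per (pathway, reference profile)."""

    COLUMNS = ["pathway", "node", "H", "p", "n_in", "n_out", "mean_r_in", "mean_r_out", "valid"]

    def __init__(self, df: pd.DataFrame):
        self.df = df.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.df)

    def get(self, pathway: str, node) -> HScoreRecord:
        sel = self.df[(self.df["pathway"] == pathway) & (self.df["node"] == node)]
        if sel.empty:
            raise KeyError((pathway, node))
        row = sel.iloc[0]
        return HScoreRecord(
            pathway=row["pathway"], node=row["node"], H=row["H"], p_value=row["p"],
            n_in=int(row["n_in"]), n_out=int(row["n_out"]),
            mean_r_in=row["mean_r_in"], mean_r_out=row["mean_r_out"], valid=bool(row["valid"]),
        )

    def for_node(self, node) -> pd.DataFrame:
        return self.df[self.df["node"] == node]


def pearson_masked(x: np.ndarray, y: np.ndarray) -> tuple[float, int]:
    """Pearson r over jointly observed entries (NaN if < 3 or degenerate)."""
    return masked_pearson(x, y)


def gene_profile_correlations(
    expr: ExpressionMatrix, profiles: np.ndarray, labels: list
) -> CorrelationMatrix:
    """Correlate every gene with every row of ``profiles`` (NaN-masked)."""
    profiles = np.atleast_2d(np.asarray(profiles, dtype=float))
    if profiles.shape[1] != len(expr.panel):
        raise ValueError("profile length does not match the cell panel")
    R, N = masked_corr_matrix(expr.values(), profiles)
    n_undef = int(np.isnan(R).sum())
    if n_undef:
        log.info("gene_profile_correlations: %d undefined entries masked", n_undef)
    return CorrelationMatrix(
        r=pd.DataFrame(R, index=expr.gene_ids, columns=labels),
        n_used=pd.DataFrame(N, index=expr.gene_ids, columns=labels),
    )


def gene_node_correlations(expr: ExpressionMatrix, model: SOMModel) -> CorrelationMatrix:
    """Genes x SOM nodes correlation matrix (the pipeline's step (a))."""
    if model.panel.cell_ids != expr.panel.cell_ids:
        raise ValueError("expression matrix and SOM model use different panels")
    return gene_profile_correlations(expr, model.codebook, list(range(model.n_nodes)))


def kruskal_wallis(group_a, group_b) -> tuple[float, float]:
    """Two-group Kruskal-Wallis H with midrank ties and tie correction.

    H = 12 / (N (N+1)) * sum_g n_g (Rbar_g - (N+1)/2)^2, divided by the tie
    correction 1 - sum(t^3 - t) / (N^3 - N); p from chi-square with 1 df.
    All values tied -> (0, 1).
    """
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty")
    values = np.concatenate([a, b])
    if not np.all(np.isfinite(values)):
        raise ValueError("groups contain non-finite values")
    N = values.size
    ranks = stats.rankdata(values)
    mean_rank = (N + 1) / 2.0
    ra = ranks[: a.size]
    rb = ranks[a.size :]
    H = (12.0 / (N * (N + 1))) * (
        a.size * (ra.mean() - mean_rank) ** 2 + b.size * (rb.mean() - mean_rank) ** 2
    )
    _, counts = np.unique(values, return_counts=True)
    tie = 1.0 - float(((counts**3 - counts).sum()) / (N**3 - N)) if N > 1 else 0.0
    if tie <= 0.0:
        return 0.0, 1.0
    H /= tie
    return float(H), float(stats.chi2.sf(H, df=1))


def pathway_h(
    corr_column: np.ndarray, membership_mask: np.ndarray, pathway: str = "", node=None
) -> HScoreRecord:
    """Signed H for one pathway against one reference profile's correlations.

    Undefined correlations are excluded from both groups before ranking; a
    pathway with fewer than 2 defined member correlations is flagged invalid.
    """
    r = np.asarray(corr_column, dtype=float)
    member = np.asarray(membership_mask, dtype=bool)
    defined = np.isfinite(r)
    r_in = r[member & defined]
    r_out = r[~member & defined]
    if len(r_in) < 2 or len(r_out) < 1:
        return HScoreRecord(pathway, node, np.nan, np.nan, len(r_in), len(r_out),
                            np.nan, np.nan, valid=False)
    H, p = kruskal_wallis(r_in, r_out)
    diff = float(r_in.mean() - r_out.mean())
    signed = math.copysign(H, diff) if diff != 0 else 0.0
    return HScoreRecord(pathway, node, signed, p, len(r_in), len(r_out),
                        float(r_in.mean()), float(r_out.mean()))


def h_score_table(corrmat: CorrelationMatrix, pathways: PathwayCollection) -> HScoreTable:
    """All pathway H-scores for every reference profile in the matrix.

    Vectorized per profile column: the column is ranked once, tie correction
    computed once, and every pathway's rank sum obtained via the boolean
    membership matrix.
    """
    genes = corrmat.gene_ids
    P = pathways.membership_matrix(genes)  # (n_pw, G)
    names = pathways.names
    Rm = corrmat.r.to_numpy()
    rows: list[tuple] = []
    for j, label in enumerate(corrmat.profile_labels):
        r = Rm[:, j]
        defined = np.isfinite(r)
        rd = r[defined]
        Nd = int(defined.sum())
        Pd = P[:, defined]
        n_in = Pd.sum(axis=1)
        n_out = Nd - n_in
        if Nd >= 2:
            ranks = stats.rankdata(rd)
            _, counts = np.unique(rd, return_counts=True)
            tie = 1.0 - float(((counts**3 - counts).sum()) / (Nd**3 - Nd))
        else:
            ranks = np.zeros(Nd)
            tie = 0.0
        mean_rank = (Nd + 1) / 2.0
        with np.errstate(invalid="ignore", divide="ignore"):
            rbar_in = (Pd @ ranks) / n_in
            rbar_out = (ranks.sum() - Pd @ ranks) / n_out
            Hu = (12.0 / (Nd * (Nd + 1))) * (
                n_in * (rbar_in - mean_rank) ** 2 + n_out * (rbar_out - mean_rank) ** 2
            ) if Nd >= 2 else np.full(len(names), np.nan)
            mean_in = (Pd @ rd) / n_in
            mean_out = (rd.sum() - Pd @ rd) / n_out
        valid = (n_in >= 2) & (n_out >= 1)
        if tie <= 0.0:
            Hu = np.zeros(len(names))
            pvals = np.ones(len(names))
        else:
            Hu = Hu / tie
            pvals = stats.chi2.sf(Hu, df=1)
        diff = mean_in - mean_out
        signed = np.where(diff == 0, 0.0, np.copysign(Hu, diff))
        for i, name in enumerate(names):
            if valid[i]:
                rows.append((name, label, float(signed[i]), float(pvals[i]),
                             int(n_in[i]), int(n_out[i]),
                             float(mean_in[i]), float(mean_out[i]), True))
            else:
                rows.append((name, label, np.nan, np.nan, int(n_in[i]), int(n_out[i]),
                             np.nan, np.nan, False))
    df = pd.DataFrame(rows, columns=HScoreTable.COLUMNS)
    return HScoreTable(df)


def top_percentile_pathways(table: HScoreTable, node, percentile: float = 10.0) -> list[str]:
    """Pathways in the topmost ``percentile`` of signed H at one node.

    The cut keeps ceil(percentile/100 * n) pathways; boundary ties are
    included. Output is ordered by H descending, name ascending on ties.
    """
    sub = table.for_node(node)
    sub = sub[sub["valid"].astype(bool) & sub["H"].notna()]
    n = len(sub)
    if n == 0:
        return []
    k = max(1, math.ceil(percentile / 100.0 * n))
    ordered = sub.sort_values(["H", "pathway"], ascending=[False, True])
    threshold = ordered["H"].iloc[k - 1]
    chosen = ordered[ordered["H"] >= threshold]
    return list(chosen["pathway"])
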