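"""LDA cross-validation, conventional baseline, method comparison, simulations.

Fisher linear discriminant analysis predicts a cell's chemo-sensitivity
class from its expression over a selected gene set; accuracy is the pooled
("consensus") fraction of cells predicted correctly across stratified
k-fold held-out partitions. The conventional baseline selects genes by
direct correlation significance, ignoring pathway structure. The comparison
harness runs pathway-derived and conventional gene sets, trimmed and
untrimmed, through identical fold partitions.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.model_selection import LeaveOneOut, StratifiedKFold

from ._stats import corr_pvalues, masked_corr_matrix
from .config import RunConfig
from .data import ChemoProfileSet, ExpressionMatrix, PathwayCollection
from .discriminate import candidate_pool, trim
from .hscore import HScoreTable, gene_profile_correlations, h_score_table, top_percentile_pathways
from .som import NodeAssignment, SOMModel, codebook_profile

log = logging.getLogger(__name__)

__all__ = [
    "ComparisonRow",
    "ConcordanceResult",
    "lda_cv_accuracy",
    "conventional_selection",
    "method_comparison",
    "pathway_overlap_concordance",
    "noise_degradation",
]


@dataclass
class ComparisonRow:
    method: str  # "pathway" | "conventional"
    trimming: str  # "trimmed" | "untrimmed"
    accuracy_mean: float
    accuracy_sd: float
    genes_mean: float
    genes_sd: float
    cells_mean: float
    cells_sd: float
    n_units: int


@dataclass
class ConcordanceResult:
    values: list[float] = field(default_factory=list)

    @property
    def mean(self) -> float:
        return float(np.mean(self.values)) if self.values else float("nan")

    @property
    def sd(self) -> float:
        return float(np.std(self.values, ddof=1)) if len(self.values) > 1 else float("nan")


def _make_lda(config: RunConfig) -> LinearDiscriminantAnalysis:
    if config.lda_shrinkage:
        return LinearDiscriminantAnalysis(solver="lsqr", shrinkage="auto")
    return LinearDiscriminantAnalysis(solver="svd")


def lda_cv_accuracy(
    features: np.ndarray,
    labels: np.ndarray,
    k: int = 5,
    seed: int = 0,
    config: RunConfig | None = None,
) -> float:
    """Consensus k-fold cross-validated LDA accuracy.

    ``features`` is a (genes x cells) sub-matrix, ``labels`` a boolean or
    binary vector per cell. Folds are stratified and shuffled by ``seed``;
    each cell is predicted exactly once by the model trained without its
    fold, and the consensus accuracy is the pooled fraction correct. With
    k >= n cells the partition degenerates to leave-one-out. Missing feature
    values are mean-imputed per gene before fitting.
    """
    config = config or RunConfig()
    X = np.asarray(features, dtype=float).T  # cells x genes
    y = np.asarray(labels).astype(int)
    n = len(y)
    if X.shape[0] != n:
        raise ValueError("labels do not match the number of cells")
    if len(np.unique(y)) < 2:
        raise ValueError("need both classes present")
    if np.isnan(X).any():
        col_mean = np.nanmean(X, axis=0)
        inds = np.where(np.isnan(X))
        X[inds] = np.take(col_mean, inds[1])
        log.info("lda_cv_accuracy: mean-imputed %d missing values", len(inds[0]))

    if k >= n:
        splits = list(LeaveOneOut().split(X, y))
    else:
        if min(np.bincount(y)) < k:
            raise ValueError("a class has fewer cells than folds")
        splits = None
        for attempt in range(10):
            skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed + attempt)
            cand = list(skf.split(X, y))
            if all(len(np.unique(y[tr])) == 2 for tr, _ in cand):
                splits = cand
                break
        if splits is None:
            raise ValueError("could not draw folds with both classes in training")

    pred = np.empty(n, dtype=int)
    for train, test in splits:
        clf = _make_lda(config)
        clf.fit(X[train], y[train])
        pred[test] = clf.predict(X[test])
    return float(np.mean(pred == y))


def conventional_selection(
    expr: ExpressionMatrix,
    chemo_profile: np.ndarray,
    mode: str = "alpha",
    value: float = 0.05,
) -> pd.DataFrame:
    """Baseline gene selection by direct correlation with the profile.

    ``alpha`` mode keeps genes with correlation p < value; ``percentile``
    mode keeps the top ``value`` percent by |r| (ceil count). Returns a
    DataFrame (gene, r, p) ordered by r ascending.
    """
    R, N = masked_corr_matrix(expr.values(), np.asarray(chemo_profile, float)[None, :])
    r = R[:, 0]
    p = corr_pvalues(R, N)[:, 0]
    genes = np.array(expr.gene_ids)
    defined = np.isfinite(r)
    df = pd.DataFrame({"gene": genes[defined], "r": r[defined], "p": p[defined]})
    if mode == "alpha":
        out = df[df["p"] < value]
    elif mode == "percentile":
        k = max(1, int(np.ceil(value / 100.0 * len(df))))
        out = df.reindex(df["r"].abs().sort_values(ascending=False).index).head(k)
    else:
        raise ValueError(f"unknown selection mode: {mode!r}")
    return out.sort_values("r", kind="mergesort").reset_index(drop=True)


def _arm_accuracy(
    expr: ExpressionMatrix,
    genes: list[str],
    cells: list[str],
    profile: np.ndarray,
    config: RunConfig,
    seed: int,
) -> float:
    sub = expr.subset(genes)
    X = sub.data.loc[:, cells].to_numpy()
    cell_pos = {c: i for i, c in enumerate(expr.panel.cell_ids)}
    y = np.array([profile[cell_pos[c]] > 0 for c in cells])
    return lda_cv_accuracy(X, y, k=config.lda_folds, seed=seed, config=config)


def method_comparison(
    expr: ExpressionMatrix,
    hscores: HScoreTable,
    pathways: PathwayCollection,
    units: dict,
    config: RunConfig | None = None,
    seed: int = 0,
) -> tuple[list[ComparisonRow], pd.DataFrame, int]:
    """Four-arm comparison (pathway/conventional x trimmed/untrimmed).

    ``units`` maps a unit label (SOM node index or compound id) to its
    reference chemoactivity profile; the H-score table must contain records
    for each unit label. All four arms of a unit share the same fold seed so
    the comparison is paired. Units whose pool is empty or whose trim fails
    are skipped and counted.
    """
    config = config or RunConfig()
    per_unit: list[dict] = []
    n_failed = 0
    for u, (label, profile) in enumerate(units.items()):
        try:
            unit_seed = seed + u
            profile = np.asarray(profile, dtype=float)
            obs_cells = [c for c, ok in zip(expr.panel.cell_ids, np.isfinite(profile)) if ok]
            pool = candidate_pool(label, hscores, expr, profile, pathways, config)
            conv = conventional_selection(
                expr, profile, config.conventional_mode, config.conventional_value
            )
            if pool.empty or conv.empty:
                raise RuntimeError("empty gene pool")
            tr_pw = trim(pool, expr, profile, config, node=label)
            tr_cv = trim(conv, expr, profile, config, node=label)
            if not (tr_pw.converged and tr_cv.converged):
                raise RuntimeError("trimming failed")
            arms = {
                ("pathway", "untrimmed"): (list(pool["gene"]), obs_cells),
                ("pathway", "trimmed"): (tr_pw.genes, tr_pw.cells),
                ("conventional", "untrimmed"): (list(conv["gene"]), obs_cells),
                ("conventional", "trimmed"): (tr_cv.genes, tr_cv.cells),
            }
            row: dict = {"unit": label}
            for (method, trimming), (genes, cells) in arms.items():
                acc = _arm_accuracy(expr, genes, cells, profile, config, unit_seed)
                row[f"{method}_{trimming}_accuracy"] = acc
                row[f"{method}_{trimming}_genes"] = len(genes)
                row[f"{method}_{trimming}_cells"] = len(cells)
            per_unit.append(row)
        except (RuntimeError, ValueError) as exc:
            n_failed += 1
            log.warning("method_comparison: unit %r skipped (%s)", label, exc)
    df = pd.DataFrame(per_unit)
    rows: list[ComparisonRow] = []
    for method in ("pathway", "conventional"):
        for trimming in ("trimmed", "untrimmed"):
            pre = f"{method}_{trimming}"
            if df.empty:
                continue
            rows.append(
                ComparisonRow(
                    method=method,
                    trimming=trimming,
                    accuracy_mean=float(df[f"{pre}_accuracy"].mean()),
                    accuracy_sd=float(df[f"{pre}_accuracy"].std(ddof=1)) if len(df) > 1 else 0.0,
                    genes_mean=float(df[f"{pre}_genes"].mean()),
                    genes_sd=float(df[f"{pre}_genes"].std(ddof=1)) if len(df) > 1 else 0.0,
                    cells_mean=float(df[f"{pre}_cells"].mean()),
                    cells_sd=float(df[f"{pre}_cells"].std(ddof=1)) if len(df) > 1 else 0.0,
                    n_units=len(df),
                )
            )
    return rows, df, n_failed


def pathway_overlap_concordance(
    model: SOMModel,
    expr: ExpressionMatrix,
    chemo: ChemoProfileSet,
    assignments: NodeAssignment,
    pathways: PathwayCollection,
    config: RunConfig | None = None,
    n_nodes: int = 100,
    members_per_node: int = 20,
    seed: int = 0,
) -> ConcordanceResult:
    """Overlap of top-decile pathways: raw compound profiles vs their SOM node.

    Randomly samples occupied nodes; for each, compares the top-decile
    pathway set obtained from the node's codebook profile with the set
    obtained from each of ``members_per_node`` member compounds' raw
    profiles (sampled with replacement when a node has fewer members). Each
    comparison contributes |top(raw) ∩ top(node)| / |top(raw)|.
    """
    config = config or RunConfig()
    rng = np.random.default_rng(seed)
    by_node: dict[int, list[str]] = {}
    for comp, node in assignments.node.items():
        by_node.setdefault(node, []).append(comp)
    eligible = sorted(by_node)
    if not eligible:
        raise ValueError("no occupied SOM nodes to sample")
    chosen = rng.choice(eligible, size=min(n_nodes, len(eligible)), replace=False)

    result = ConcordanceResult()
    for node in chosen:
        node = int(node)
        node_corr = gene_profile_correlations(
            expr, codebook_profile(model, node)[None, :], [node]
        )
        node_top = set(
            top_percentile_pathways(h_score_table(node_corr, pathways), node,
                                    config.h_top_percentile)
        )
        if not node_top:
            continue
        members = by_node[node]
        replace = len(members) < members_per_node
        if replace:
            log.info("node %d has %d members; sampling with replacement", node, len(members))
        picks = rng.choice(members, size=members_per_node, replace=replace)
        for comp in picks:
            raw = chemo.profile(str(comp))
            corr = gene_profile_correlations(expr, raw[None, :], [comp])
            raw_top = set(
                top_percentile_pathways(h_score_table(corr, pathways), comp,
                                        config.h_top_percentile)
            )
            if not raw_top:
                continue
            result.values.append(len(raw_top & node_top) / len(raw_top))
    return result


def noise_degradation(
    expr: ExpressionMatrix,
    target_mean_pairwise_r: float,
    refit_gene_count,
    baseline_gene_count: int,
    seed: int = 0,
    tol: float = 0.02,
    max_bisect: int = 60,
) -> tuple[ExpressionMatrix, float]:
    """White-noise degradation calibrated to a target original-vs-degraded r.

    Gaussian noise is added to every observed expression value; its sd is
    bisected until the mean per-gene Pearson correlation between the original
    and degraded vectors is within ``tol`` of the target. The discriminating
    gene set is then recomputed on the degraded matrix via the caller-supplied
    ``refit_gene_count(degraded_expr) -> int`` and the gene-count ratio
    degraded/baseline is returned alongside the degraded matrix.
    """
    if not (0.0 < target_mean_pairwise_r < 1.0):
        raise ValueError("target correlation must be in (0, 1)")
    from .synthetic import degrade  # local import: avoids a module cycle

    def mean_corr(sigma: float) -> tuple[float, ExpressionMatrix]:
        deg = degrade(expr, sigma, seed=seed)
        A, B = expr.values(), deg.values()
        rs = []
        for a, b in zip(A, B):
            m = np.isfinite(a) & np.isfinite(b)
            if m.sum() >= 3 and np.std(a[m]) > 0 and np.std(b[m]) > 0:
                rs.append(np.corrcoef(a[m], b[m])[0, 1])
        return float(np.mean(rs)), deg

    lo, hi = 0.0, 1.0
    while mean_corr(hi)[0] > target_mean_pairwise_r:
        hi *= 2.0
        if hi > 1e6:
            raise ValueError("target correlation unreachable by added noise")
    achieved, deg = mean_corr(hi)
    for _ in range(max_bisect):
        mid = 0.5 * (lo + hi)
        achieved, deg = mean_corr(mid)
        if abs(achieved - target_mean_pairwise_r) <= tol:
            break
        if achieved > target_mean_pairwise_r:
            lo = mid
        else:
            hi = mid
    else:
        raise ValueError(
            f"bisection did not reach target {target_mean_pairwise_r}; achieved {achieved:.3f}"
        )
    ratio = refit_gene_count(deg) / baseline_gene_count
    return deg, float(ratio)
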