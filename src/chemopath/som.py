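"""Self-organizing map over chemoactivity profiles, tolerant of missing data.

A rectangular grid of prototype ("codebook") vectors is fit to the
normalized compound profiles. Each node's codebook vector is the
representative GI50 profile of its compound cluster and is the reference
profile for all downstream gene-correlation work. Distances are masked
Euclidean: the mean squared difference over a profile's observed cells, so
profiles with different missingness compare fairly.

Training is batch-style with a Gaussian neighborhood whose radius decays
linearly from max(rows, cols)/2 to below one grid step, and a blending rate
decaying from 0.5 to 0.01 over the epochs. With a fixed seed, training is bit-reproducible.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .config import RunConfig
from .data import CellPanel, ChemoProfileSet

log = logging.getLogger(__name__)

__all__ = [
    "SOMModel",
    "NodeAssignment",
    "train_som",
    "assign_node",
    "assign_all",
    "codebook_profile",
    "project_scores",
    "quantization_error",
]


@dataclass
class SOMModel:
    rows: int
    cols: int
    codebook: np.ndarray  # (rows*cols, n_cells), row-major node order, no NaN
    panel: CellPanel
    train_params: dict = field(default_factory=dict)
    seed: int = 0
    qe_history: list[float] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.codebook.shape != (self.rows * self.cols, len(self.panel)):
            raise ValueError("codebook shape does not match grid and panel")
        if not np.all(np.isfinite(self.codebook)):
            raise ValueError("codebook vectors must be finite")

    @property
    def n_nodes(self) -> int:
        return self.rows * self.cols

    def node_rc(self, node: int) -> tuple[int, int]:
        return divmod(node, self.cols)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "rows": self.rows,
            "cols": self.cols,
            "cell_ids": list(self.panel.cell_ids),
            "codebook": self.codebook.tolist(),
            "train_params": self.train_params,
            "seed": self.seed,
            "qe_history": self.qe_history,
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def from_json(cls, path: str | Path) -> "SOMModel":
        payload = json.loads(Path(path).read_text())
        return cls(
            rows=payload["rows"],
            cols=payload["cols"],
            codebook=np.asarray(payload["codebook"], dtype=float),
            panel=CellPanel(tuple(payload["cell_ids"])),
            train_params=payload.get("train_params", {}),
            seed=payload.get("seed", 0),
            qe_history=payload.get("qe_history", []),
        )


@dataclass
class NodeAssignment:
    """Best-matching-unit index and quantization distance per compound."""

    node: dict[str, int]
    distance: dict[str, float]


def _masked_sq_dist(X: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Mean squared difference over observed entries, rows of X vs rows of C.

    C must be fully observed. Returns (n_samples, n_nodes).
    """
    M = np.isfinite(X)
    X0 = np.where(M, X, 0.0)
    n_obs = M.sum(axis=1, keepdims=True).astype(float)
    if np.any(n_obs == 0):
        raise ValueError("profile with no observed entries")
    # sum over observed j of (x_j - c_j)^2 = sum x^2 - 2 x.c + sum_obs c^2
    d2 = (
        (X0 * X0).sum(axis=1, keepdims=True)
        - 2.0 * X0 @ C.T
        + M.astype(float) @ (C * C).T
    )
    return np.maximum(d2, 0.0) / n_obs


def _grid_sq_dist(rows: int, cols: int) -> np.ndarray:
    rr, cc = np.divmod(np.arange(rows * cols), cols)
    return (rr[:, None] - rr[None, :]) ** 2 + (cc[:, None] - cc[None, :]) ** 2


def train_som(
    profiles: ChemoProfileSet,
    config: RunConfig | None = None,
    *,
    rows: int | None = None,
    cols: int | None = None,
    epochs: int | None = None,
    seed: int | None = None,
) -> SOMModel:
    """Fit a rows x cols batch SOM to the profile set.

    Keyword overrides take precedence over ``config``. Raises on an empty
    profile set or non-finite (infinite) values; NaN means missing and is
    handled by masking.
    """
    config = config or RunConfig()
    rows = rows if rows is not None else config.som_rows
    cols = cols if cols is not None else config.som_cols
    epochs = epochs if epochs is not None else config.som_epochs
    seed = seed if seed is not None else config.rng_seed
    if rows < 1 or cols < 1:
        raise ValueError("grid dimensions must be >= 1")
    X = profiles.values()
    if X.shape[0] < 1:
        raise ValueError("need at least one profile to train")
    if np.any(np.isinf(X)):
        raise ValueError("profiles contain non-finite values")
    n_nodes = rows * cols
    n_cells = X.shape[1]
    rng = np.random.default_rng(seed)

    # init: data rows in greedy farthest-point order (so distinct response
    # groups seed distinct prototypes), missing entries filled with the
    # cell-line mean; cycled with random re-draws when nodes outnumber rows
    col_mean = np.nanmean(X, axis=0)
    col_mean = np.where(np.isfinite(col_mean), col_mean, 0.0)
    filled = np.where(np.isfinite(X), X, col_mean)
    order = [int(rng.integers(X.shape[0]))]
    min_d = ((filled - filled[order[0]]) ** 2).mean(axis=1)
    while len(order) < min(n_nodes, X.shape[0]):
        nxt = int(np.argmax(min_d))
        order.append(nxt)
        min_d = np.minimum(min_d, ((filled - filled[nxt]) ** 2).mean(axis=1))
    idx = np.array(order)
    if n_nodes > len(idx):
        extra = rng.choice(X.shape[0], size=n_nodes - len(idx), replace=True)
        idx = np.concatenate([idx, extra])
    codebook = filled[idx].copy()
    codebook += 1e-6 * rng.standard_normal(codebook.shape)  # break exact ties

    grid_d2 = _grid_sq_dist(rows, cols)
    M = np.isfinite(X)
    X0 = np.where(M, X, 0.0)
    MF = M.astype(float)

    # final neighborhood shrinks below one grid step so that neighboring
    # prototypes decouple and nodes can specialize to distinct clusters
    radius0 = max(rows, cols) / 2.0
    radius_final = 0.3
    qe_history: list[float] = []
    for epoch in range(epochs):
        frac = epoch / max(epochs - 1, 1)
        radius = max(radius0 + (radius_final - radius0) * frac, 1e-9)
        lr = config.som_lr_initial + (config.som_lr_final - config.som_lr_initial) * frac
        lr = lr if epochs > 1 else config.som_lr_initial

        d2 = _masked_sq_dist(X, codebook)
        bmu = np.argmin(d2, axis=1)
        qe_history.append(float(np.mean(np.sqrt(d2[np.arange(len(bmu)), bmu]))))

        H = np.exp(-grid_d2[:, bmu] / (2.0 * radius * radius))  # (nodes, samples)
        num = H @ X0
        den = H @ MF
        touched = den > 1e-12
        target = np.where(touched, num / np.where(touched, den, 1.0), codebook)
        codebook = codebook + lr * (target - codebook)

    model = SOMModel(
        rows=rows,
        cols=cols,
        codebook=codebook,
        panel=profiles.panel,
        train_params={
            "epochs": epochs,
            "lr_initial": config.som_lr_initial,
            "lr_final": config.som_lr_final,
            "radius_initial": radius0,
        },
        seed=seed,
        qe_history=qe_history,
    )
    return model


def assign_node(model: SOMModel, profile: np.ndarray) -> int:
    """Best-matching unit for one profile; ties break to the lowest index."""
    profile = np.asarray(profile, dtype=float)
    if not np.any(np.isfinite(profile)):
        raise ValueError("cannot assign an all-missing profile")
    d2 = _masked_sq_dist(profile[None, :], model.codebook)[0]
    return int(np.argmin(d2))


def assign_all(model: SOMModel, profiles: ChemoProfileSet) -> NodeAssignment:
    X = profiles.values()
    d2 = _masked_sq_dist(X, model.codebook)
    bmu = np.argmin(d2, axis=1)
    dist = np.sqrt(d2[np.arange(len(bmu)), bmu])
    ids = profiles.compound_ids
    return NodeAssignment(
        node={c: int(k) for c, k in zip(ids, bmu)},
        distance={c: float(d) for c, d in zip(ids, dist)},
    )


def codebook_profile(model: SOMModel, node: int) -> np.ndarray:
    """The node's representative chemoactivity profile (length = panel size)."""
    if not (0 <= node < model.n_nodes):
        raise IndexError(f"node {node} out of range 0..{model.n_nodes - 1}")
    return model.codebook[node].copy()


def project_scores(model: SOMModel, node_scores: dict[int, float]) -> np.ndarray:
    """Spread per-node scores on the (rows, cols) grid; unscored nodes are NaN."""
    grid = np.full(model.n_nodes, np.nan)
    for node, score in node_scores.items():
        if not (0 <= node < model.n_nodes):
            raise IndexError(f"node {node} out of range")
        grid[node] = score
    return grid.reshape(model.rows, model.cols)


def quantization_error(model: SOMModel, profiles: ChemoProfileSet) -> float:
    """Mean masked distance from each profile to its best-matching unit."""
    X = profiles.values()
    d2 = _masked_sq_dist(X, model.codebook)
    return float(np.mean(np.sqrt(d2.min(axis=1))))
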