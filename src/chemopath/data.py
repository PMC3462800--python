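"""Domain containers for the chemoactivity-expression mining pipeline.

The pipeline works on three aligned objects: a panel of tumor cell lines, a
gene x cell constitutive-expression matrix, and a compound x cell
chemoactivity (GI50-derived) matrix. Gene sets ("pathways") connect the
expression rows to curated biology. Missing entries are NaN throughout;
``DataFrame.isna()`` is the missingness mask.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator, Mapping, NamedTuple

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "CellPanel",
    "ExpressionMatrix",
    "ChemoProfileSet",
    "Pathway",
    "PathwayCollection",
]


@dataclass(frozen=True)
class CellPanel:
    """An ordered panel of unique tumor cell-line identifiers.

    The panel fixes the column dimension (and column order) of every matrix
    in a run; positional alignment is preserved through all stages.
    """

    cell_ids: tuple[str, ...]
    tissue: tuple[str, ...] | None = None

    def __post_init__(self) -> None:
        if len(self.cell_ids) < 2:
            raise ValueError("a cell panel needs at least 2 cell lines")
        if len(set(self.cell_ids)) != len(self.cell_ids):
            dupes = sorted({c for c in self.cell_ids if list(self.cell_ids).count(c) > 1})
            raise ValueError(f"duplicate cell identifiers: {dupes}")
        if self.tissue is not None and len(self.tissue) != len(self.cell_ids):
            raise ValueError("tissue labels must match panel length")

    def __len__(self) -> int:
        return len(self.cell_ids)

    def __iter__(self) -> Iterator[str]:
        return iter(self.cell_ids)

    def index_of(self, cell_id: str) -> int:
        return self.cell_ids.index(cell_id)


def _check_frame(data: pd.DataFrame, panel: CellPanel, what: str) -> pd.DataFrame:
    if list(data.columns) != list(panel.cell_ids):
        raise ValueError(f"{what} columns do not match the cell panel")
    if data.index.has_duplicates:
        dupes = sorted(data.index[data.index.duplicated()].unique())
        raise ValueError(f"duplicate {what} row keys: {dupes}")
    return data.astype(float)


@dataclass
class ExpressionMatrix:
    """Gene x cell constitutive expression values (NaN = missing).

    Every retained gene must have at least 3 observed values so that a
    correlation against a chemoactivity profile is defined.
    """

    data: pd.DataFrame
    panel: CellPanel

    def __post_init__(self) -> None:
        self.data = _check_frame(self.data, self.panel, "gene")
        n_obs = self.data.notna().sum(axis=1)
        bad = n_obs[n_obs < 3]
        if len(bad):
            raise ValueError(
                f"genes with fewer than 3 observed values: {sorted(bad.index[:5])}"
            )

    @property
    def gene_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_genes(self) -> int:
        return len(self.data)

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def subset(self, genes: Iterable[str]) -> "ExpressionMatrix":
        genes = [g for g in genes if g in self.data.index]
        return ExpressionMatrix(self.data.loc[genes], self.panel)


@dataclass
class ChemoProfileSet:
    """Compound x cell GI50-derived chemoactivity values (NaN = missing).

    Sign convention (after normalization): positive z-score = chemo-sensitive
    cell, negative = chemo-insensitive.
    """

    data: pd.DataFrame
    panel: CellPanel
    normalized: bool = False

    _TOL = 1e-8

    def __post_init__(self) -> None:
        self.data = _check_frame(self.data, self.panel, "compound")
        if self.normalized:
            vals = self.data.to_numpy()
            mean = np.nanmean(vals, axis=1)
            sd = np.nanstd(vals, axis=1, ddof=1)
            checkable = np.isfinite(sd) & (sd > 0)
            if np.any(np.abs(mean[checkable]) > self._TOL) or np.any(
                np.abs(sd[checkable] - 1.0) > 1e-6
            ):
                raise ValueError("normalized flag set but profiles are not z-scores")

    @property
    def compound_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def n_compounds(self) -> int:
        return len(self.data)

    def values(self) -> np.ndarray:
        return self.data.to_numpy()

    def profile(self, compound_id: str) -> np.ndarray:
        return self.data.loc[compound_id].to_numpy()


class Pathway(NamedTuple):
    name: str
    description: str
    genes: frozenset[str]
    source: str = ""


@dataclass
class PathwayCollection:
    """Named gene sets (KEGG / Biocarta / GO style), unique by name."""

    pathways: dict[str, Pathway] = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name, pw in self.pathways.items():
            if not pw.genes:
                raise ValueError(f"pathway {name!r} has an empty gene set")

    @classmethod
    def from_pathways(cls, pathways: Iterable[Pathway]) -> "PathwayCollection":
        out: dict[str, Pathway] = {}
        for pw in pathways:
            if pw.name in out:
                raise ValueError(f"duplicate pathway name: {pw.name!r}")
            out[pw.name] = pw
        return cls(out)

    def __len__(self) -> int:
        return len(self.pathways)

    def __iter__(self) -> Iterator[Pathway]:
        return iter(self.pathways.values())

    def __contains__(self, name: str) -> bool:
        return name in self.pathways

    def __getitem__(self, name: str) -> Pathway:
        return self.pathways[name]

    @property
    def names(self) -> list[str]:
        return list(self.pathways)

    def membership_matrix(self, gene_order: list[str]) -> np.ndarray:
        """Boolean (n_pathways, n_genes) membership indicator in given order."""
        gene_pos: Mapping[str, int] = {g: i for i, g in enumerate(gene_order)}
        M = np.zeros((len(self.pathways), len(gene_order)), dtype=bool)
        for i, pw in enumerate(self.pathways.values()):
            for g in pw.genes:
                j = gene_pos.get(g)
                if j is not None:
                    M[i, j] = True
        return M
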