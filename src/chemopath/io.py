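"""Readers and writers: TSV matrices, GMT gene sets, tabular reports.

Matrix files are tab-separated with cell identifiers in the first row and
row keys (gene symbols or compound ids) in the first column; empty cells and
"NA" are missing. Gene-set files follow the standard GMT dialect: one set
per line, ``name<TAB>description<TAB>member...``.
"""
from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import pandas as pd

from .data import CellPanel, ChemoProfileSet, ExpressionMatrix, Pathway, PathwayCollection

log = logging.getLogger(__name__)

__all__ = ["read_matrix", "write_matrix", "read_gmt", "write_gmt", "write_table"]

_NA_TOKENS = ["", "NA"]


def _check_rectangular(path: Path) -> int:
    """Verify constant field count per line; return the number of columns."""
    width = None
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            n = line.rstrip("\n").count("\t") + 1
            if width is None:
                width = n
            elif n != width:
                raise ValueError(
                    f"{path}: ragged row at line {lineno} "
                    f"({n} fields, expected {width})"
                )
    if width is None:
        raise ValueError(f"{path}: empty file")
    return width


def read_matrix(path: str | Path, kind: str) -> ExpressionMatrix | ChemoProfileSet:
    """Read a genes-or-compounds x cells TSV matrix into a typed container.

    ``kind`` is ``"expression"`` or ``"chemoactivity"``. Duplicate row keys
    and ragged rows are rejected with the offending key / line number.
    """
    path = Path(path)
    if kind not in ("expression", "chemoactivity"):
        raise ValueError(f"unknown matrix kind: {kind!r}")
    _check_rectangular(path)
    df = pd.read_csv(
        path,
        sep="\t",
        index_col=0,
        na_values=_NA_TOKENS,
        keep_default_na=False,
        dtype=str,
    )
    df.index = df.index.astype(str).str.strip()
    df.columns = df.columns.astype(str).str.strip()
    if df.index.has_duplicates:
        dupes = sorted(df.index[df.index.duplicated()].unique())
        raise ValueError(f"{path}: duplicate row keys: {dupes}")
    df = df.apply(pd.to_numeric)
    panel = CellPanel(tuple(df.columns))
    if kind == "expression":
        return ExpressionMatrix(df, panel)
    return ChemoProfileSet(df, panel, normalized=False)


def write_matrix(obj: ExpressionMatrix | ChemoProfileSet, path: str | Path) -> None:
    """Write a matrix container back to TSV (missing entries as empty cells)."""
    obj.data.to_csv(path, sep="\t", na_rep="", float_format="%.6g")


def read_gmt(path: str | Path) -> PathwayCollection:
    """Read a GMT gene-set file; duplicate member symbols are collapsed."""
    path = Path(path)
    pathways: list[Pathway] = []
    seen: set[str] = set()
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line.strip():
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(
                    f"{path}: line {lineno} has {len(fields)} fields (need >= 3)"
                )
            name = fields[0].strip()
            if name in seen:
                raise ValueError(f"{path}: duplicate pathway name {name!r} at line {lineno}")
            seen.add(name)
            members = frozenset(g.strip() for g in fields[2:] if g.strip())
            if not members:
                raise ValueError(f"{path}: pathway {name!r} at line {lineno} has no members")
            source = name.split("_", 1)[0].upper() if "_" in name else ""
            pathways.append(Pathway(name, fields[1].strip(), members, source))
    return PathwayCollection.from_pathways(pathways)


def write_gmt(collection: PathwayCollection, path: str | Path) -> None:
    with open(path, "w") as fh:
        for pw in collection:
            fh.write("\t".join([pw.name, pw.description, *sorted(pw.genes)]) + "\n")


def write_table(records: pd.DataFrame | list[dict], path: str | Path, columns=None) -> None:
    """Write a report table as TSV with a deterministic column order.

    Floats are rendered at 6 significant digits so that re-reading recovers
    the values within 1e-6 relative tolerance.
    """
    if not isinstance(records, pd.DataFrame):
        records = pd.DataFrame(list(records), columns=columns)
    elif columns is not None:
        records = records[list(columns)]
    records.to_csv(path, sep="\t", index=False, na_rep="", float_format="%.6g")


def read_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values=_NA_TOKENS, keep_default_na=False)
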