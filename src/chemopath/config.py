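"""Run configuration: every printed threshold of the procedure in one place."""
from __future__ import annotations

import dataclasses
from dataclasses import dataclass
from pathlib import Path

import yaml

__all__ = ["RunConfig"]


@dataclass
class RunConfig:
    """Tunable thresholds and stochastic-stage seeds.

    Defaults follow the published procedure: profiles must report more than
    ``min_cells_reported`` cell lines and have CV >= ``min_cv``; the SOM grid
    is 54 x 37 (1998 nodes); pathways in the topmost ``h_top_percentile`` of
    H-scores seed the candidate pool; correlation admission and iterative
    trimming both use nominal p < 0.05; LDA is 5-fold cross-validated;
    enrichment requires at least ``min_overlap`` shared genes.
    """

    min_cells_reported: int = 40
    min_cv: float = 0.05
    som_rows: int = 54
    som_cols: int = 37
    som_epochs: int = 50
    som_lr_initial: float = 0.5
    som_lr_final: float = 0.01
    h_top_percentile: float = 10.0
    corr_alpha: float = 0.05
    trim_alpha: float = 0.05
    lda_folds: int = 5
    min_overlap: int = 2
    min_pathway_genes: int = 2
    max_iter: int = 100
    rng_seed: int = 0
    # ambiguous-procedure switches (documented defaults)
    stage1_mode: str = "zscore"  # or "center": first normalization pass per cell line
    equal_var_t: bool = True  # pooled-variance Student's t; False = Welch
    lda_shrinkage: bool = False
    conventional_mode: str = "alpha"  # or "percentile"
    conventional_value: float = 0.05

    def __post_init__(self) -> None:
        for name in ("min_cv", "corr_alpha", "trim_alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be in (0, 1), got {v}")
        if not (0.0 < self.h_top_percentile <= 100.0):
            raise ValueError("h_top_percentile must be in (0, 100]")
        if self.som_rows < 1 or self.som_cols < 1:
            raise ValueError("SOM grid dimensions must be >= 1")
        if self.lda_folds < 2:
            raise ValueError("lda_folds must be >= 2")
        if self.stage1_mode not in ("zscore", "center"):
            raise ValueError("stage1_mode must be 'zscore' or 'center'")
        if self.conventional_mode not in ("alpha", "percentile"):
            raise ValueError("conventional_mode must be 'alpha' or 'percentile'")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**raw)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)
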