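"""Workflow orchestration: normalize -> SOM -> H-scores -> discriminate -> enrich.

``run_pipeline`` executes the stages in dependency order against files in a
working directory, records a run manifest (config snapshot, seed, stage
timings, input/output digests) and skips stages whose inputs are unchanged
unless forced. The evaluate stage's conventional arm deliberately bypasses
the H-score stage.
"""
from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from . import io as cio
from .config import RunConfig
from .discriminate import candidate_pool, trim
from .enrich import enrichment_report, report_frame
from .hscore import gene_node_correlations, h_score_table
from .normalize import normalize_pipeline
from .som import SOMModel, assign_all, codebook_profile, train_som
from .synthetic import generate_panel

log = logging.getLogger(__name__)

__all__ = ["RunManifest", "run_pipeline", "STAGES"]

STAGES = ("simulate", "normalize", "som", "hscore", "discriminate", "enrich")


@dataclass
class RunManifest:
    config: dict
    seed: int
    stages: dict[str, dict] = field(default_factory=dict)

    def record(self, stage: str, status: str, elapsed: float,
               inputs: dict[str, str], outputs: dict[str, str]) -> None:
        self.stages[stage] = {
            "status": status,
            "elapsed_s": round(elapsed, 3),
            "inputs": inputs,
            "outputs": outputs,
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(
            {"config": self.config, "seed": self.seed, "stages": self.stages}, indent=2
        ))


def _digest(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def _digests(paths: list[Path]) -> dict[str, str]:
    return {p.name: _digest(p) for p in paths if p.exists()}


def _stage_fresh(
    manifest_path: Path, stage: str, inputs: list[Path], outputs: list[Path], workdir: Path
) -> bool:
    """True when a previous run recorded identical input digests and outputs exist."""
    if not manifest_path.exists() or not all(p.exists() for p in outputs):
        return False
    try:
        prev = json.loads(manifest_path.read_text())["stages"].get(stage)
    except (json.JSONDecodeError, KeyError):
        return False
    if not prev or prev.get("status") not in ("completed", "skipped (up to date)"):
        return False
    if not all((workdir / name).exists() for name in prev.get("outputs", {})):
        return False
    return prev.get("inputs") == _digests(inputs)


def run_pipeline(
    workdir: str | Path,
    config: RunConfig | None = None,
    stages: tuple[str, ...] | None = None,
    simulate: bool = False,
    force: bool = False,
) -> RunManifest:
    """Run the requested stages (default: all applicable) in ``workdir``.

    Expects/produces: E.tsv, C.tsv, P.gmt (inputs; written by the simulate
    stage), then C.norm.tsv / E.filt.tsv / P.filt.gmt / report.json,
    som.json, hscores.tsv, dset.<node>.json and enrichment.<node>.tsv.
    A stage failure halts downstream stages and is recorded.
    """
    config = config or RunConfig()
    workdir = Path(workdir)
    workdir.mkdir(parents=True, exist_ok=True)
    wanted = tuple(stages) if stages else STAGES
    if not simulate:
        wanted = tuple(s for s in wanted if s != "simulate")
    manifest_path = workdir / "manifest.json"
    manifest = RunManifest(config=config.to_dict(), seed=config.rng_seed)

    paths = {
        "E": workdir / "E.tsv", "C": workdir / "C.tsv", "P": workdir / "P.gmt",
        "truth": workdir / "truth.json",
        "Cn": workdir / "C.norm.tsv", "Ef": workdir / "E.filt.tsv",
        "Pf": workdir / "P.filt.gmt", "report": workdir / "report.json",
        "som": workdir / "som.json", "hs": workdir / "hscores.tsv",
    }
    io_map: dict[str, tuple[list[Path], list[Path]]] = {
        "simulate": ([], [paths["E"], paths["C"], paths["P"], paths["truth"]]),
        "normalize": ([paths["E"], paths["C"], paths["P"]],
                      [paths["Cn"], paths["Ef"], paths["Pf"], paths["report"]]),
        "som": ([paths["Cn"]], [paths["som"]]),
        "hscore": ([paths["Ef"], paths["Pf"], paths["som"]], [paths["hs"]]),
        "discriminate": ([paths["Ef"], paths["Pf"], paths["som"], paths["hs"], paths["Cn"]], []),
        "enrich": ([paths["Ef"], paths["Pf"]], []),
    }

    halted = False
    for stage in STAGES:
        if stage not in wanted:
            continue
        inputs, outputs = io_map[stage]
        if halted:
            manifest.record(stage, "skipped (upstream failure)", 0.0, {}, {})
            continue
        if not force and _stage_fresh(manifest_path, stage, inputs, outputs, workdir):
            prev = json.loads(manifest_path.read_text())["stages"][stage]
            manifest.stages[stage] = dict(prev, status="skipped (up to date)")
            continue
        t0 = time.perf_counter()
        try:
            extra = _execute(stage, paths, config, workdir)
            manifest.record(stage, "completed", time.perf_counter() - t0,
                            _digests(inputs), _digests(outputs + extra))
        except Exception as exc:  # recorded, halts downstream
            log.error("stage %s failed: %s", stage, exc)
            manifest.record(stage, f"failed: {exc}", time.perf_counter() - t0,
                            _digests(inputs), {})
            halted = True
    manifest.to_json(manifest_path)
    return manifest


def _execute(stage: str, paths: dict[str, Path], config: RunConfig, workdir: Path) -> list[Path]:
    """Run one stage; returns extra output paths not in the static map."""
    if stage == "simulate":
        expr, chemo, pw, truth = generate_panel(seed=config.rng_seed)
        cio.write_matrix(expr, paths["E"])
        cio.write_matrix(chemo, paths["C"])
        cio.write_gmt(pw, paths["P"])
        truth.to_json(paths["truth"])
        return []

    if stage == "normalize":
        chemo = cio.read_matrix(paths["C"], "chemoactivity")
        expr = cio.read_matrix(paths["E"], "expression")
        pw = cio.read_gmt(paths["P"])
        norm, expr_f, pw_f, report = normalize_pipeline(chemo, expr, pw, config)
        cio.write_matrix(norm, paths["Cn"])
        cio.write_matrix(expr_f, paths["Ef"])
        cio.write_gmt(pw_f, paths["Pf"])
        paths["report"].write_text(json.dumps(report.to_dict()))
        return []

    if stage == "som":
        norm = cio.read_matrix(paths["Cn"], "chemoactivity")
        model = train_som(norm, config)
        model.to_json(paths["som"])
        return []

    if stage == "hscore":
        expr_f = cio.read_matrix(paths["Ef"], "expression")
        pw_f = cio.read_gmt(paths["Pf"])
        model = SOMModel.from_json(paths["som"])
        corr = gene_node_correlations(expr_f, model)
        table = h_score_table(corr, pw_f)
        cio.write_table(table.df, paths["hs"])
        return []

    if stage == "discriminate":
        expr_f = cio.read_matrix(paths["Ef"], "expression")
        pw_f = cio.read_gmt(paths["Pf"])
        model = SOMModel.from_json(paths["som"])
        norm = cio.read_matrix(paths["Cn"], "chemoactivity")
        table_df = cio.read_table(paths["hs"])
        from .hscore import HScoreTable

        table = HScoreTable(table_df)
        occupied = sorted(set(assign_all(model, norm).node.values()))
        extra: list[Path] = []
        for node in occupied:
            profile = codebook_profile(model, node)
            pool = candidate_pool(node, table, expr_f, profile, pw_f, config)
            if pool.empty:
                log.warning("node %d: empty candidate pool", node)
                continue
            dset = trim(pool, expr_f, profile, config, node=node)
            out = workdir / f"dset.{node}.json"
            out.write_text(json.dumps(dset.to_dict()))
            extra.append(out)
        return extra

    if stage == "enrich":
        expr_f = cio.read_matrix(paths["Ef"], "expression")
        pw_f = cio.read_gmt(paths["Pf"])
        extra = []
        for dset_path in sorted(workdir.glob("dset.*.json")):
            payload = json.loads(dset_path.read_text())
            if not payload.get("converged") or not payload["genes"]:
                continue
            records = enrichment_report(payload["genes"], pw_f, expr_f.gene_ids, config)
            node = dset_path.stem.split(".")[1]
            out = workdir / f"enrichment.{node}.tsv"
            cio.write_table(report_frame(records), out)
            extra.append(out)
        return extra

    raise ValueError(f"unknown stage: {stage}")
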