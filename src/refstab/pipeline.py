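"""End-to-end orchestration: screen -> stability -> optimal count -> validation.

The pipeline mirrors the workflow of a reference-gene determination study:
candidate genes are screened from an FPKM matrix, their qPCR stability is
ranked by four algorithms and aggregated, the geNorm V-series decides how
many references are needed, and target genes are re-normalized against the
chosen (and, for contrast, arbitrary) references.  Every stage writes plain
TSV/JSON outputs and a provenance block so a run is reproducible from
inputs + config + seed.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from datetime import datetime, timezone
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .errors import ConfigError, RefstabError
from .qpcr import (
    CqMatrix,
    QcRule,
    collapse_replicates,
    fit_standard_curve,
    normalize_expression,
    qc_check,
    read_cq_table,
    read_dilution_series,
    read_sample_annotation,
)
from .screen import (
    ExpressionMatrix,
    ScreeningConfig,
    read_expression_table,
    screen_candidates,
    top_candidates,
    top_k_overlap,
)
from .simulate import SimulationConfig, GeneClassSpec, simulate_cq, simulate_fpkm
from .stability import DEFAULT_METHODS, StabilityReport, evaluate_panel

logger = logging.getLogger(__name__)

__all__ = [
    "PipelineConfig",
    "run_screen",
    "run_stability",
    "run_validation",
    "run_qc",
    "write_report",
    "run_all",
]

_FLOAT_FMT = "%.6g"


@dataclass
class PipelineConfig:
    out_dir: Path
    fpkm_path: Path | None = None
    tissue_path: Path | None = None
    cq_path: Path | None = None
    annotation_path: Path | None = None
    dilution_path: Path | None = None
    screening: ScreeningConfig = field(default_factory=ScreeningConfig)
    qc: QcRule = field(default_factory=QcRule)
    methods: tuple[str, ...] = DEFAULT_METHODS
    panel: str | list[str] = "screen"  # "screen", "all" or explicit gene ids
    exclude_genes: list[str] = field(default_factory=list)
    efficiency_base: float = 2.0
    m_threshold: float = 0.5
    v_threshold: float = 0.15
    validation_targets: list[str] = field(default_factory=list)
    validation_references: list[str] = field(default_factory=list)
    unstable_reference: str | None = None
    seed: int = 0
    simulate: SimulationConfig | None = None

    def __post_init__(self) -> None:
        self.out_dir = Path(self.out_dir)
        for name in ("fpkm_path", "tissue_path", "cq_path", "annotation_path", "dilution_path"):
            val = getattr(self, name)
            if val is not None:
                setattr(self, name, Path(val))
        if self.m_threshold <= 0 or self.v_threshold <= 0:
            raise ConfigError("thresholds must be positive")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: Mapping) -> "PipelineConfig":
        raw = dict(raw)
        if "screening" in raw and isinstance(raw["screening"], Mapping):
            raw["screening"] = ScreeningConfig(**raw["screening"])
        if "qc" in raw and isinstance(raw["qc"], Mapping):
            qc = dict(raw["qc"])
            if "efficiency_range" in qc:
                qc["efficiency_range"] = tuple(qc["efficiency_range"])
            raw["qc"] = QcRule(**qc)
        if "simulate" in raw and isinstance(raw["simulate"], Mapping):
            sim = dict(raw["simulate"])
            sim["gene_classes"] = [
                GeneClassSpec(**c) for c in sim.get("gene_classes", [])
            ]
            raw["simulate"] = SimulationConfig(**sim)
        if "methods" in raw:
            raw["methods"] = tuple(raw["methods"])
        return cls(**raw)

    def echo(self) -> dict:
        def clean(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: clean(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, Path):
                return str(obj)
            if isinstance(obj, (list, tuple)):
                return [clean(v) for v in obj]
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            return obj

        return clean(self)


def _write_tsv(df: pd.DataFrame, path: Path, index: bool = False) -> None:
    df.to_csv(path, sep="\t", float_format=_FLOAT_FMT, index=index)


def _load_expression(cfg: PipelineConfig) -> ExpressionMatrix:
    if cfg.fpkm_path is None or cfg.tissue_path is None:
        raise ConfigError("run_screen needs fpkm_path and tissue_path")
    return read_expression_table(cfg.fpkm_path, cfg.tissue_path)


def _load_cq(cfg: PipelineConfig) -> CqMatrix:
    if cfg.cq_path is None or cfg.annotation_path is None:
        raise ConfigError("run_stability needs cq_path and annotation_path")
    return read_cq_table(cfg.cq_path, cfg.annotation_path)


def run_simulation(cfg: PipelineConfig) -> dict:
    """Generate synthetic inputs into the output directory and point the
    config's input paths at them."""
    if cfg.simulate is None:
        raise ConfigError("no simulation section in the configuration")
    out = cfg.out_dir
    out.mkdir(parents=True, exist_ok=True)
    matrix, truth = simulate_fpkm(cfg.simulate)
    cq = simulate_cq(cfg.simulate, truth)
    fpkm_path = out / "fpkm.tsv"
    tissue_path = out / "tissues.tsv"
    cq_path = out / "cq.tsv"
    annotation_path = out / "samples.tsv"
    _write_tsv(matrix.values.rename_axis("gene_id"), fpkm_path, index=True)
    pd.DataFrame(
        {"sample_id": matrix.sample_ids,
         "tissue": [matrix.tissue_of[s] for s in matrix.sample_ids]}
    ).to_csv(tissue_path, sep="\t", index=False, header=False)
    _write_tsv(cq.cq.rename_axis("gene_id"), cq_path, index=True)
    ann = pd.DataFrame(
        {"sample_id": cq.sample_ids,
         "group": [cq.group_of[s] for s in cq.sample_ids]}
    )
    if cq.replicate_of is not None:
        ann["biological_sample"] = [cq.replicate_of[s] for s in cq.sample_ids]
    ann.to_csv(annotation_path, sep="\t", index=False)
    (out / "truth.json").write_text(truth.to_json())
    cfg.fpkm_path, cfg.tissue_path = fpkm_path, tissue_path
    cfg.cq_path, cfg.annotation_path = cq_path, annotation_path
    return {
        "status": "ok",
        "n_genes": matrix.n_genes,
        "n_samples": len(matrix.sample_ids),
        "files": [str(p) for p in (fpkm_path, tissue_path, cq_path, annotation_path)],
    }


def run_screen(cfg: PipelineConfig) -> dict:
    """Screen the FPKM table; writes screening.tsv, candidates.txt, overlap.json."""
    matrix = _load_expression(cfg)
    stats = screen_candidates(matrix, cfg.screening)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    _write_tsv(stats, cfg.out_dir / "screening.tsv")
    candidates = top_candidates(stats, cfg.screening.top_k) if len(stats) else []
    (cfg.out_dir / "candidates.txt").write_text("\n".join(candidates) + "\n")
    overlap = None
    if len(stats) >= 1:
        k = min(cfg.screening.top_k, len(stats))
        overlap = top_k_overlap(stats, k)
        (cfg.out_dir / "overlap.json").write_text(
            json.dumps(overlap, indent=2, sort_keys=True)
        )
    return {
        "status": "ok",
        "n_screened": len(stats),
        "candidates": candidates,
        "overlap_sizes": overlap["sizes"] if overlap else None,
    }


def run_qc(cfg: PipelineConfig) -> dict:
    """Fit standard curves from the dilution table and QC them."""
    if cfg.dilution_path is None:
        return {"status": "not_run", "reason": "no dilution series supplied"}
    rows = []
    for series in read_dilution_series(cfg.dilution_path):
        fit = fit_standard_curve(series)
        rows.append(
            {
                "gene_id": fit.gene_id,
                "slope": fit.slope,
                "intercept": fit.intercept,
                "r_squared": fit.r_squared,
                "efficiency_percent": fit.efficiency_percent,
                "qc_flags": ";".join(qc_check(fit, cfg.qc)) or "pass",
            }
        )
    table = pd.DataFrame(rows)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    _write_tsv(table, cfg.out_dir / "standard_curves.tsv")
    return {
        "status": "ok",
        "n_curves": len(rows),
        "failed_qc": [r["gene_id"] for r in rows if r["qc_flags"] != "pass"],
    }


def _resolve_panel(cfg: PipelineConfig, cq: CqMatrix, screen_out: dict | None) -> list[str]:
    if isinstance(cfg.panel, (list, tuple)):
        panel = list(cfg.panel)
    elif cfg.panel == "all":
        panel = list(cq.gene_ids)
    elif cfg.panel == "screen":
        if screen_out and screen_out.get("candidates"):
            panel = [g for g in screen_out["candidates"] if g in cq.gene_ids]
        else:
            logger.warning("no screening candidates available; using all Cq genes")
            panel = list(cq.gene_ids)
    else:
        raise ConfigError(f"panel must be 'screen', 'all' or a gene list, not {cfg.panel!r}")
    unknown = [g for g in panel if g not in cq.gene_ids]
    if unknown:
        raise ConfigError(f"panel genes absent from the Cq table: {unknown}")
    for gene in cfg.exclude_genes:
        if gene in panel:
            logger.info("excluding gene %s from the stability panel (configured)", gene)
            panel.remove(gene)
    return panel


def run_stability(cfg: PipelineConfig, screen_out: dict | None = None) -> dict:
    """Rank the panel with the configured methods; writes the stability
    table, the geNorm M trajectory and the V series."""
    cq = _load_cq(cfg)
    panel = _resolve_panel(cfg, cq, screen_out)
    report = evaluate_panel(
        cq,
        panel=panel,
        efficiency_base=cfg.efficiency_base,
        methods=cfg.methods,
        v_threshold=cfg.v_threshold,
    )
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    _write_tsv(report.table.rename_axis("gene_id"), cfg.out_dir / "stability_table.tsv", index=True)
    if report.genorm is not None:
        traj_rows = [
            {"step": i, "panel_size": len(step["panel"]), "gene_id": g, "m": m}
            for i, step in enumerate(report.genorm.m_trajectory)
            for g, m in sorted(step["m_values"].items())
        ]
        _write_tsv(pd.DataFrame(traj_rows), cfg.out_dir / "m_trajectory.tsv")
        v_rows = pd.DataFrame(
            {"n": list(report.v_series), "v": list(report.v_series.values())}
        )
        _write_tsv(v_rows, cfg.out_dir / "v_series.tsv")
    summary = {
        "status": "ok" if len(report.failures) < len(cfg.methods) else "failed",
        "panel": panel,
        "failures": report.failures,
        "optimal_n": report.optimal_n,
        "optimal_flag": report.optimal_flag,
        "v_series": {str(k): v for k, v in report.v_series.items()},
        "ranking": report.table.index.tolist() if len(report.table) else [],
    }
    if report.genorm is not None:
        summary["genorm_stable_genes"] = report.genorm.stable_genes(cfg.m_threshold)
    return summary


def run_validation(cfg: PipelineConfig) -> dict:
    """Normalize each validation target against every single reference, the
    combined reference set and (optionally) a designated unstable
    reference; writes a tidy validation.tsv."""
    if not cfg.validation_targets or not cfg.validation_references:
        return {"status": "not_run", "reason": "no validation targets/references"}
    cq = _load_cq(cfg)
    if cq.replicate_of is not None:
        cq = collapse_replicates(cq)
    known = set(cq.gene_ids)
    for gene in (
        cfg.validation_targets
        + cfg.validation_references
        + ([cfg.unstable_reference] if cfg.unstable_reference else [])
    ):
        if gene not in known:
            raise ConfigError(f"unknown gene id in validation settings: {gene!r}")
    rows = []
    schemes: list[tuple[str, list[str]]] = [
        (ref, [ref]) for ref in cfg.validation_references
    ]
    if len(cfg.validation_references) > 1:
        schemes.append(("combined", list(cfg.validation_references)))
    if cfg.unstable_reference:
        schemes.append((cfg.unstable_reference, [cfg.unstable_reference]))
    for target in cfg.validation_targets:
        for scheme, refs in schemes:
            res = normalize_expression(cq.cq.loc[target], cq.cq.loc[refs])
            for sample in res.index:
                rows.append(
                    {
                        "target": target,
                        "reference": scheme,
                        "sample_id": sample,
                        "group": cq.group_of[sample],
                        "delta_ct": res.loc[sample, "delta_ct"],
                        "expression": res.loc[sample, "expression"],
                    }
                )
    table = pd.DataFrame(rows)
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    _write_tsv(table, cfg.out_dir / "validation.tsv")
    return {
        "status": "ok",
        "targets": cfg.validation_targets,
        "schemes": [s for s, _ in schemes],
    }


def write_report(cfg: PipelineConfig, stages: Mapping[str, Mapping]) -> Path:
    """Write the run report (JSON) with a provenance block."""
    if not any(s.get("status") == "ok" for s in stages.values()):
        logger.warning("writing a report although no stage completed")
    report = {
        "provenance": {
            "package": "refstab",
            "version": __version__,
            "seed": cfg.seed,
            "config": cfg.echo(),
            "timestamp": datetime.now(timezone.utc).isoformat(),
        },
        "stages": {
            name: dict(out) if out else {"status": "not_run"}
            for name, out in stages.items()
        },
    }
    cfg.out_dir.mkdir(parents=True, exist_ok=True)
    path = cfg.out_dir / "report.json"
    path.write_text(json.dumps(report, indent=2, sort_keys=True, default=str))
    return path


def run_all(cfg: PipelineConfig) -> dict:
    """Full workflow; stage failures are recorded, later stages still run
    where their inputs allow."""
    stages: dict[str, dict] = {}
    if cfg.simulate is not None:
        stages["simulate"] = run_simulation(cfg)
    for name, fn, needs_screen in (
        ("screen", run_screen, False),
        ("qc", run_qc, False),
        ("stability", run_stability, True),
        ("validation", run_validation, False),
    ):
        try:
            stages[name] = (
                fn(cfg, stages.get("screen")) if needs_screen else fn(cfg)
            )
        except RefstabError as exc:
            logger.error("stage %s failed: %s", name, exc)
            stages[name] = {"status": "failed", "error": str(exc)}
    write_report(cfg, stages)
    return stages
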