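"""End-to-end analysis pipeline and run manifest.

Stage order follows the study's analysis sequence: (1) per-analyte
threshold biomarkers on the long + short samples, (2) the
multidimensional forest biomarker, (3) trend tests across all three
ordered PFS groups plus the total-immune / PFS correlation, (4)
correlation matrices, (5) per-analyte expression-quartile survival.
Each run writes six report files plus a manifest recording input
checksums, the seed, package versions, and per-stage wall time.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cohort import Cohort, CohortError, read_cohort, total_immune
from .multidim import ForestParams, build_multidim_biomarker, default_grid
from .stats import correlation_matrix, cuzick_trend, spearman
from .survival import logrank_hr, parse_survival_records, quartile_groups
from .thresholds import analyte_table, reports_to_frame

__all__ = ["RunConfig", "run_pipeline", "PipelineError"]

#: Gene analytes highlighted as top differentially expressed; default
#: rows of the gene x gene correlation matrix.
TOP_GENES = ("LAG3", "ICOS", "CTLA4", "PD-1", "PD-L1", "TNFRSF18")

GROUP_ORDER = ("short", "intermediate", "long")


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    matrix: str | None = None
    meta: str | None = None
    kinds: str | None = None
    outdir: str = "immunomark_out"
    endpoint: str = "pfs"
    use_alt_months: bool = False
    seed: int = 0
    top_k: int = 5
    forest: dict = field(default_factory=dict)       # ForestParams overrides
    grid: list | None = None                          # list of param dicts
    quartile_n: int | None = None
    corr_genes: tuple[str, ...] = TOP_GENES
    stages: tuple[str, ...] = ("analytes", "biomarker", "trend",
                               "correlate", "survival")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise PipelineError("config", f"unknown config keys: {sorted(unknown)}")
        if "corr_genes" in raw:
            raw["corr_genes"] = tuple(raw["corr_genes"])
        if "stages" in raw:
            raw["stages"] = tuple(raw["stages"])
        return cls(**raw)

    def forest_params(self) -> ForestParams:
        return ForestParams(**self.forest)

    def grid_params(self, subset_size: int) -> list[ForestParams]:
        if self.grid is None:
            return default_grid(subset_size)
        return [ForestParams(**g) for g in self.grid]


def _sha256(path: str | Path) -> str:
    h = hashlib.sha256()
    h.update(Path(path).read_bytes())
    return h.hexdigest()


def run_pipeline(config: RunConfig, cohort: Cohort | None = None) -> dict:
    """Run all configured stages; returns (and writes) the run manifest."""
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "version": __version__,
        "seed": config.seed,
        "endpoint": config.endpoint,
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in vars(config).items()},
        "inputs": {},
        "stages": {},
        "timing": {"started": time.time(), "stage_seconds": {}},
    }
    if cohort is None:
        try:
            if not (config.matrix and config.meta and config.kinds):
                raise CohortError("matrix, meta and kinds paths are all required")
            cohort = read_cohort(config.matrix, config.meta, config.kinds)
        except (CohortError, OSError) as exc:
            raise PipelineError("load", str(exc)) from exc
        manifest["inputs"] = {
            name: {"path": str(p), "sha256": _sha256(p)}
            for name, p in (("matrix", config.matrix), ("meta", config.meta),
                            ("kinds", config.kinds))
        }
    manifest["n_samples"] = len(cohort.records)
    manifest["n_analytes"] = len(cohort.matrix.columns)

    def timed(stage: str):
        class _T:
            def __enter__(self):
                self.t0 = time.perf_counter()

            def __exit__(self, exc_type, exc, tb):
                manifest["timing"]["stage_seconds"][stage] = (
                    time.perf_counter() - self.t0)
                if exc is not None and not isinstance(exc, PipelineError):
                    raise PipelineError(stage, str(exc)) from exc
        return _T()

    reports = None
    if "analytes" in config.stages:
        with timed("analytes"):
            reports = analyte_table(cohort)
            frame = reports_to_frame(reports)
            frame.to_csv(outdir / "analyte_table.tsv", sep="\t", index=False)
            manifest["stages"]["analytes"] = {
                "file": "analyte_table.tsv", "rows": len(frame)}

    if "biomarker" in config.stages:
        with timed("biomarker"):
            if reports is None:
                reports = analyte_table(cohort)
            ranking, search, model, roc = build_multidim_biomarker(
                cohort, reports, top_k=config.top_k,
                defaults=config.forest_params(),
                grid=config.grid_params(0) if config.grid is not None else None,
                master_seed=config.seed)
            report = {
                "ranking": list(ranking.analytes),
                "subset_loo_errors": {
                    "|".join(k): v for k, v in search.loo_errors.items()},
                "chosen_subset": list(model.subset),
                "grid_winner": vars(model.params).copy(),
                "grid_errors": model.grid_errors,
                "scores": {sid: float(s) for sid, s
                           in zip(model.sample_ids, model.loo_scores)},
                "classes": dict(zip(model.sample_ids, model.loo_classes)),
                "confusion": vars(model.counts).copy(),
                "metrics": model.metrics.rounded(),
                "auc": roc.auc,
            }
            (outdir / "biomarker_report.json").write_text(
                json.dumps(report, indent=2, sort_keys=True))
            pd.DataFrame({"fpr": roc.fpr, "tpr": roc.tpr}).to_csv(
                outdir / "roc_points.tsv", sep="\t", index=False)
            manifest["stages"]["biomarker"] = {
                "file": "biomarker_report.json",
                "chosen_subset": list(model.subset),
                "loo_error": int(model.counts.fn + model.counts.fp),
                "auc": roc.auc,
            }

    if "trend" in config.stages:
        with timed("trend"):
            groups = cohort.groups()
            labeled = groups.dropna()
            order = [g for g in GROUP_ORDER if (labeled == g).any()]
            rows = []
            for analyte in cohort.analytes():
                v = cohort.values(analyte).loc[labeled.index]
                res = cuzick_trend(v.to_numpy(), labeled.to_numpy(), order=order)
                med = {f"median_{g}": float(np.median(v[labeled == g]))
                       for g in order}
                rows.append({"analyte": analyte, "T": res.T, "z": res.z,
                             "p": res.p, **med})
            pd.DataFrame(rows).to_csv(outdir / "trend.tsv", sep="\t", index=False)
            ti = [total_immune(cohort, sid) for sid in cohort.matrix.index]
            pfs = [r.pfs.months for r in cohort.records]
            pair = spearman(ti, pfs)
            manifest["stages"]["trend"] = {
                "file": "trend.tsv",
                "total_immune_pfs_spearman": {
                    "r": pair.r, "p": pair.p, "n": pair.n},
            }

    if "correlate" in config.stages:
        with timed("correlate"):
            genes = [g for g in config.corr_genes
                     if g in cohort.matrix.columns]
            cells = cohort.analytes("cell_percent")
            gg = correlation_matrix(cohort, genes, genes)
            frames = [gg.to_long().assign(block="gene_gene")]
            if cells:
                gc = correlation_matrix(cohort, genes, cells)
                frames.append(gc.to_long().assign(block="gene_cell"))
            pd.concat(frames, ignore_index=True).to_csv(
                outdir / "correlations.tsv", sep="\t", index=False)
            manifest["stages"]["correlate"] = {
                "file": "correlations.tsv", "genes": genes, "cells": cells}

    if "survival" in config.stages:
        with timed("survival"):
            records = parse_survival_records(
                cohort, endpoint=config.endpoint,
                use_alt_months=config.use_alt_months)
            by_id = dict(zip(cohort.matrix.index, records))
            rows = []
            for analyte in cohort.analytes("gene_tpm"):
                expr = cohort.values(analyte)
                low, high = quartile_groups(
                    expr.to_numpy(), ids=expr.index,
                    n_per_group=config.quartile_n)
                res = logrank_hr([by_id[i] for i in high],
                                 [by_id[i] for i in low])
                rows.append({
                    "analyte": analyte,
                    "hr": "-" if res.hr is None else res.hr,
                    "ci_low": "-" if res.ci95 is None else res.ci95[0],
                    "ci_high": "-" if res.ci95 is None else res.ci95[1],
                    "p": res.p,
                    "n_high": len(high), "n_low": len(low),
                })
            pd.DataFrame(rows).to_csv(outdir / "survival.tsv", sep="\t",
                                      index=False)
            manifest["stages"]["survival"] = {
                "file": "survival.tsv", "rows": len(rows)}

    manifest["timing"]["finished"] = time.time()
    (outdir / "manifest.json").write_text(
        json.dumps(manifest, indent=2, sort_keys=True, default=str))
    return manifest
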