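"""Configuration-driven orchestration of the full analysis.

Runs thermal -> susceptibility -> spatial -> covariates -> model ->
scenarios in order on a bundle of CSV inputs, writing per-stage CSV/JSON
outputs plus a manifest (input hashes, seed, durations) into a run
directory.  A stage whose outputs already exist under an unchanged
manifest entry is skipped, so runs resume from the first stale stage.
Structured log lines record counts of records dropped per exclusion rule
so attrition through the pipeline is auditable.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import covariates as cov
from . import model as mdl
from . import scenarios as scn
from . import spatial as spa
from . import susceptibility as sus
from . import thermal as thm

logger = logging.getLogger(__name__)

STAGES = ["thermal", "susceptibility", "spatial", "covariates", "model", "scenarios"]


@dataclass
class RunConfig:
    """Paths, thresholds and model options for one pipeline run."""

    surveys: str
    sst: str
    site_indices: str
    score_table: str
    out_dir: str
    synonyms: str = ""
    zones: str = ""
    cluster_km: float = spa.CLUSTER_THRESHOLD_KM
    min_cells: int = spa.MIN_CELLS_PER_ZONE_DEPTH
    min_surveys_per_taxon: int = sus.MIN_SURVEYS_PER_TAXON
    min_accumulating_hotspot: float = thm.DEFAULT_MIN_ACCUMULATING_HOTSPOT
    transform_overrides: "dict[str, str]" = field(default_factory=dict)
    manageable_drivers: "list[str]" = field(
        default_factory=lambda: list(scn.DEFAULT_MANAGEABLE_DRIVERS)
    )
    dhw_quantile: float = scn.SCENARIO_DHW_QUANTILE
    driver_columns: "list[str]" = field(default_factory=lambda: list(cov.DRIVER_COLUMNS))
    interaction_anchors: "list[str]" = field(
        default_factory=lambda: list(mdl.DEFAULT_INTERACTION_ANCHORS)
    )
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        return cls(**raw)

    def input_paths(self) -> "dict[str, str]":
        out = {"surveys": self.surveys, "sst": self.sst,
               "site_indices": self.site_indices, "score_table": self.score_table}
        if self.synonyms:
            out["synonyms"] = self.synonyms
        if self.zones:
            out["zones"] = self.zones
        return out


def validate_inputs(config: RunConfig) -> "list[dict]":
    """Schema checks for all input files; empty issue list iff runnable."""
    issues: list[dict] = []
    for name, path in config.input_paths().items():
        if not Path(path).exists():
            issues.append({"file": name, "issue": "missing_file", "detail": path})
    if issues:
        return issues

    surveys = pd.read_csv(config.surveys)
    required = {"survey_id", "lat", "lon", "depth_m", "total_cover",
                "pct_bleached", "taxon", "cover"}
    missing = required - set(surveys.columns)
    if missing:
        issues.append({"file": "surveys", "issue": "missing_columns",
                       "detail": ",".join(sorted(missing))})
        return issues
    for col in ("total_cover", "pct_bleached", "cover", "depth_m", "lat", "lon"):
        bad = pd.to_numeric(surveys[col], errors="coerce").isna() & surveys[col].notna()
        for idx in surveys.index[bad]:
            issues.append({"file": "surveys", "issue": "non_numeric",
                           "detail": f"row {idx}, column {col}"})
    numeric = surveys.assign(
        cover=pd.to_numeric(surveys["cover"], errors="coerce"),
        total_cover=pd.to_numeric(surveys["total_cover"], errors="coerce"),
    )
    sums = numeric.groupby("survey_id").agg(
        taxa_cover=("cover", "sum"), total=("total_cover", "first")
    )
    for sid, row in sums.iterrows():
        if np.isfinite(row.taxa_cover) and np.isfinite(row.total) and (
            row.taxa_cover > row.total + 1e-6
        ):
            issues.append({"file": "surveys", "issue": "cover_inconsistent",
                           "detail": str(sid)})

    table = sus.SusceptibilityTable.from_csv(config.score_table)
    synonyms = _read_synonyms(config.synonyms)
    for taxon in sorted(set(surveys["taxon"].astype(str))):
        resolved = synonyms.get(taxon, taxon)
        try:
            table.resolve(resolved)
        except sus.UnresolvableTaxonError:
            issues.append({"file": "surveys", "issue": "taxon_unscored", "detail": taxon})

    sst = pd.read_csv(config.sst)
    if not {"island_id", "date", "sst"} <= set(sst.columns):
        issues.append({"file": "sst", "issue": "missing_columns",
                       "detail": "island_id,date,sst"})
    return issues


def _read_synonyms(path: str) -> "dict[str, str]":
    if not path:
        return {}
    frame = pd.read_csv(path)
    return dict(zip(frame["from"].astype(str), frame["to"].astype(str)))


def _hash_file(path) -> str:
    h = hashlib.sha256()
    with open(path, "rb") as fh:
        for chunk in iter(lambda: fh.read(65536), b""):
            h.update(chunk)
    return h.hexdigest()


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: str):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


def run_pipeline(config: RunConfig, resume: bool = True) -> Path:
    """Execute all stages; returns the run directory.

    Stage outputs are deterministic functions of the inputs and config, so
    a rerun with unchanged inputs reproduces byte-identical files.
    """
    issues = validate_inputs(config)
    if issues:
        first = issues[0]
        raise PipelineError("ingest", f"{first['issue']} ({first['detail']})")

    run_dir = Path(config.out_dir)
    run_dir.mkdir(parents=True, exist_ok=True)
    manifest_path = run_dir / "manifest.json"
    manifest = {"seed": config.seed, "inputs": {}, "stages": {}}
    if resume and manifest_path.exists():
        with open(manifest_path) as fh:
            manifest = json.load(fh)
    input_hashes = {k: _hash_file(v) for k, v in config.input_paths().items()}
    if manifest.get("inputs") != input_hashes:
        manifest = {"seed": config.seed, "inputs": input_hashes, "stages": {}}

    state: dict = {}
    for stage in STAGES:
        outputs = _stage_outputs(stage, run_dir)
        done = manifest["stages"].get(stage)
        # model/scenarios are cheap deterministic refits; always recompute so
        # downstream stages have the in-memory fitted model available
        resumable = stage not in ("model", "scenarios")
        if resume and resumable and done and all(Path(p).exists() for p in outputs.values()):
            logger.info("stage %s: outputs current, skipping", stage)
            state.update(_load_stage(stage, outputs, config))
            continue
        t0 = time.perf_counter()
        try:
            state.update(_run_stage(stage, config, state, outputs))
        except PipelineError:
            raise
        except Exception as exc:  # halt with stage name + first actionable cause
            raise PipelineError(stage, str(exc)) from exc
        manifest["stages"][stage] = {
            "outputs": {k: str(v) for k, v in outputs.items()},
            "duration_s": round(time.perf_counter() - t0, 4),
        }
        with open(manifest_path, "w") as fh:
            json.dump(manifest, fh, indent=2)
    return run_dir


def _stage_outputs(stage: str, run_dir: Path) -> "dict[str, Path]":
    table = {
        "thermal": {"island_metrics": run_dir / "island_metrics.csv"},
        "susceptibility": {"survey_scores": run_dir / "survey_scores.csv"},
        "spatial": {"cells": run_dir / "cells.csv"},
        "covariates": {
            "driver_matrix": run_dir / "driver_matrix.csv",
            "registry": run_dir / "transform_registry.json",
            "dropped": run_dir / "dropped_cells.csv",
        },
        "model": {
            "coefficients": run_dir / "model_coefficients.csv",
            "summary": run_dir / "model_summary.json",
        },
        "scenarios": {
            "perturbations": run_dir / "perturbations.csv",
            "management": run_dir / "management_scenario.csv",
        },
    }
    return table[stage]


def _survey_level(surveys: pd.DataFrame) -> pd.DataFrame:
    cols = [c for c in ("survey_id", "island", "zone", "lat", "lon", "date",
                        "depth_m", "method", "total_cover", "pct_bleached")
            if c in surveys.columns]
    return surveys[cols].drop_duplicates("survey_id").reset_index(drop=True)


def _run_stage(stage: str, config: RunConfig, state: dict, outputs: "dict[str, Path]") -> dict:
    if stage == "thermal":
        series_list = thm.read_sst_csv(config.sst)
        metrics = [
            thm.compute_dhw(
                s,
                thm.compute_mmm(s, list(s.years[:-1]) or list(s.years)),
                min_accumulating_hotspot=config.min_accumulating_hotspot,
            )
            for s in series_list
        ]
        table = thm.island_metrics_table(metrics)
        out = table.copy()
        out["max_dhw"] = out["max_dhw"].round(6)
        out.to_csv(outputs["island_metrics"], index=False)
        return {"island_metrics": table}

    surveys_long = pd.read_csv(config.surveys)
    if stage == "susceptibility":
        synonyms = _read_synonyms(config.synonyms)
        rows = sus.apply_synonyms(surveys_long, synonyms)
        table = sus.SusceptibilityTable.from_csv(config.score_table)
        scores = sus.score_surveys(rows, table)
        scores.to_csv(outputs["survey_scores"], index=False)
        return {"survey_scores": scores, "surveys_long": rows}

    if stage == "spatial":
        scores = state["survey_scores"]
        surveys = _survey_level(surveys_long).merge(
            scores[["survey_id", "bs"]], on="survey_id", how="inner"
        )
        clusters = spa.cluster_surveys(surveys, threshold_km=config.cluster_km)
        cells = spa.aggregate_cells(surveys, clusters)
        if config.zones:
            zone_map = dict(pd.read_csv(config.zones)[["cluster_id", "zone"]].values)
            cells = spa.assign_zones(cells, zone_map={int(k): str(v) for k, v in zone_map.items()})
        cells = spa.filter_zone_depth(cells, min_cells=config.min_cells)
        cells["weight"] = spa.compute_weights(cells)
        cells.to_csv(outputs["cells"], index=False)
        return {"cells": cells}

    if stage == "covariates":
        cells = state["cells"]
        if "mean_bs" in cells.columns and "bs_score" not in cells.columns:
            # the community susceptibility driver is the cell's mean BS
            cells = cells.rename(columns={"mean_bs": "bs_score"})
        site_indices = pd.read_csv(config.site_indices)
        matrix = cov.build_driver_matrix(
            cells,
            site_indices=site_indices,
            transform_overrides=config.transform_overrides,
            driver_columns=config.driver_columns,
        )
        analysis = pd.concat([matrix.cells, matrix.design], axis=1)
        analysis["sqrt_pct_bleached"] = np.sqrt(analysis["mean_pct_bleached"])
        analysis.to_csv(outputs["driver_matrix"], index=False)
        matrix.registry.to_json(outputs["registry"])
        matrix.dropped.to_csv(outputs["dropped"], index=False)
        return {"analysis": analysis, "registry": matrix.registry}

    if stage == "model":
        analysis = state["analysis"]
        drivers = [c for c in config.driver_columns if c in analysis.columns]
        spec = mdl.ModelSpec(
            response="sqrt_pct_bleached",
            drivers=drivers,
            anchors=tuple(config.interaction_anchors),
        )
        fitted = mdl.stepwise_bic(spec, analysis, registry=state.get("registry"))
        fitted.coefficient_table().to_csv(outputs["coefficients"], index=False)
        with open(outputs["summary"], "w") as fh:
            json.dump(
                {"terms": fitted.terms, "n": fitted.n, "bic": fitted.bic,
                 "adj_r2": fitted.adj_r2}, fh, indent=2,
            )
        return {"fitted": fitted, "analysis": analysis}

    if stage == "scenarios":
        fitted = state["fitted"]
        analysis = state["analysis"]
        perturb = scn.perturb_model(fitted)
        perturb.to_csv(outputs["perturbations"], index=False)
        manageable = tuple(
            d for d in config.manageable_drivers if d in scn.model_drivers(fitted)
        ) or tuple(config.manageable_drivers)
        mgmt = scn.management_scenario(
            fitted, analysis, manageable=manageable, dhw_quantile=config.dhw_quantile
        )
        mgmt.to_csv(outputs["management"], index=False)
        return {"perturbations": perturb, "management": mgmt}

    raise PipelineError(stage, "unknown stage")


def _read_exact(path) -> pd.DataFrame:
    # round_trip parsing so resumed stages see bit-identical floats
    return pd.read_csv(path, float_precision="round_trip")


def _load_stage(stage: str, outputs: "dict[str, Path]", config: RunConfig) -> dict:
    """Reload a completed stage's outputs for downstream resume."""
    if stage == "thermal":
        return {"island_metrics": _read_exact(outputs["island_metrics"])}
    if stage == "susceptibility":
        return {
            "survey_scores": _read_exact(outputs["survey_scores"]),
            "surveys_long": _read_exact(config.surveys),
        }
    if stage == "spatial":
        return {"cells": _read_exact(outputs["cells"])}
    if stage == "covariates":
        return {
            "analysis": _read_exact(outputs["driver_matrix"]),
            "registry": cov.TransformRegistry.from_json(outputs["registry"]),
        }
    return {}
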