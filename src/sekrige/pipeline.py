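"""Configured end-to-end pipeline: simulate/load -> fit -> krige -> map ->
validate -> tables.

A run is driven by a YAML config and is deterministic under fixed seeds:
identical configs produce identical artifacts.  Every stage writes its
artifact before the next stage starts, and a manifest records the config
hash, seeds, package version, and per-stage wall time.
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
from shapely.geometry import mapping, shape
from shapely.geometry.base import BaseGeometry

from . import __version__
from .exceedance import ThresholdSet, VerbalScale, map_exceedance
from .kriging import build_grid, krige_grid
from .prevalence import prevalence_below, render_table, summarize_groups
from .reml import DEFAULT_NU_GRID, FittedModel, profile_smoothness
from .synthetic import (
    SURVEY_COLUMNS,
    GenerativeParams,
    default_region,
    generate_design,
    simulate_survey,
)
from .validation import loo_crossvalidate, median_sspe_interval, sspe_summary

logger = logging.getLogger("sekrige")

__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "read_survey_csv",
    "write_survey_csv",
    "read_region_geojson",
    "write_region_geojson",
]

REQUIRED_COLUMNS = SURVEY_COLUMNS


def read_survey_csv(path) -> pd.DataFrame:
    """Read and validate a survey table.

    The header must contain the documented schema columns; extra columns
    are preserved untouched.  Malformed rows are reported with their file
    row number (1-based, header = row 1).
    """
    df = pd.read_csv(path)
    missing = [c for c in REQUIRED_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    se = pd.to_numeric(df["plasma_se"], errors="coerce")
    bad = df.index[~(se > 0) | ~np.isfinite(se)].tolist()
    if bad:
        rows = [i + 2 for i in bad[:10]]
        raise ValueError(
            f"{path}: non-positive or non-numeric plasma_se at rows {rows}"
        )
    for col in ("x", "y"):
        v = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[~np.isfinite(v)].tolist()
        if bad:
            raise ValueError(
                f"{path}: non-finite {col} at rows {[i + 2 for i in bad[:10]]}"
            )
    df["plasma_se"] = se
    return df


def write_survey_csv(table: pd.DataFrame, path) -> None:
    table.to_csv(path, index=False)


def read_region_geojson(path) -> BaseGeometry:
    with open(path) as fh:
        gj = json.load(fh)
    if gj.get("type") == "FeatureCollection":
        geoms = [shape(f["geometry"]) for f in gj["features"]]
        if not geoms:
            raise ValueError(f"{path}: empty FeatureCollection")
        geom = geoms[0]
        for g in geoms[1:]:
            geom = geom.union(g)
    elif gj.get("type") == "Feature":
        geom = shape(gj["geometry"])
    else:
        geom = shape(gj)
    if geom.is_empty:
        raise ValueError(f"{path}: empty geometry")
    return geom


def write_region_geojson(geom: BaseGeometry, path) -> None:
    with open(path, "w") as fh:
        json.dump(
            {"type": "Feature", "properties": {}, "geometry": mapping(geom)}, fh
        )


@dataclass
class PipelineConfig:
    """Validated configuration of a full analysis run.

    Either ``survey_csv`` points at observed data, or ``synthetic`` holds
    the generator settings.  All defaults mirror the reference analysis:
    natural-log transform, smoothness grid profile likelihood, thresholds
    84.9 / 64.8 / 30 ng/mL, and a desk-scale 5 km grid (the production
    analysis used 0.5 km).
    """

    out_dir: str = "sekrige_run"
    survey_csv: str | None = None
    boundary_geojson: str | None = None
    synthetic: dict = field(
        default_factory=lambda: {
            "n_clusters": 102,
            "urban_fraction": 18 / 102,
            "households_per_cluster": 9,
            "individuals_per_household": 2,
        }
    )
    nu_grid: tuple = DEFAULT_NU_GRID
    n_starts: int = 3
    grid_resolution_km: float = 5.0
    thresholds: dict = field(
        default_factory=lambda: {"GPx3": 84.9, "IDI": 64.8, "KD": 30.0}
    )
    verbal_edges: tuple = (0.10, 0.33, 0.66, 0.90)
    seed: int = 20_15
    n_sim_validation: int = 100

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config fields: {sorted(unknown)}")
        cfg = cls(**raw)
        cfg.validate()
        return cfg

    def validate(self) -> None:
        if self.grid_resolution_km <= 0:
            raise ValueError("grid_resolution_km must be positive")
        if not isinstance(self.seed, (int, np.integer)):
            raise ValueError("seed must be an integer")
        for name in ("survey_csv", "boundary_geojson"):
            p = getattr(self, name)
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(f"config field {name}: no such file {p}")

    def content_hash(self) -> str:
        payload = json.dumps(
            {k: _jsonable(getattr(self, k)) for k in self.__dataclass_fields__},
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def _jsonable(v):
    if isinstance(v, tuple):
        return list(v)
    return v


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages and return the run manifest.

    Stages: survey, fit, krige, map, validate, tables.  A stage failure
    aborts the run with the stage name; artifacts of completed stages are
    kept on disk.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config_hash": config.content_hash(),
        "seed": int(config.seed),
        "version": __version__,
        "stages": [],
    }
    rng_seeds = np.random.SeedSequence(config.seed).spawn(4)

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            logger.info("stage %s ...", name)
            try:
                fn()
            except Exception as exc:
                _write_manifest(out, manifest)
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            manifest["stages"].append(
                {"name": name, "seconds": round(time.perf_counter() - t0, 3)}
            )

        return deco

    state: dict = {}

    @stage("survey")
    def _survey():
        if config.boundary_geojson:
            region = read_region_geojson(config.boundary_geojson)
        else:
            region = default_region()
        state["region"] = region
        if config.survey_csv:
            table = read_survey_csv(config.survey_csv)
        else:
            syn = config.synthetic
            design = generate_design(
                n_clusters=syn["n_clusters"],
                urban_fraction=syn["urban_fraction"],
                households_per_cluster=syn["households_per_cluster"],
                individuals_per_household=syn["individuals_per_household"],
                region=region,
                seed=_derive(rng_seeds[0]),
            )
            state["design"] = design
            table = simulate_survey(
                design, GenerativeParams.malawi_like(), seed=_derive(rng_seeds[1])
            )
        state["table"] = table
        write_survey_csv(table, out / "survey.csv")

    @stage("fit")
    def _fit():
        model = profile_smoothness(
            state["table"], nu_grid=config.nu_grid, n_starts=config.n_starts
        )
        state["model"] = model
        model.save(out / "fitted_model.json")

    @stage("krige")
    def _krige():
        grid = build_grid(state["region"], config.grid_resolution_km)
        preds = krige_grid(grid, state["table"], state["model"])
        state["preds"] = preds
        preds.to_csv(out / "grid_predictions.csv", index=False)

    @stage("map")
    def _map():
        thresholds = ThresholdSet(dict(config.thresholds))
        scale = VerbalScale(edges=tuple(config.verbal_edges))
        emap = map_exceedance(state["preds"], thresholds, scale)
        emap.to_csv(out / "exceedance_map.csv", index=False)
        with open(out / "legend.json", "w") as fh:
            json.dump(scale.to_legend(), fh, indent=2)

    @stage("validate")
    def _validate():
        cv = loo_crossvalidate(state["table"], state["model"])
        cv.to_csv(out / "cv_table.csv", index=False)
        summary = sspe_summary(cv)
        result = {
            "median_sspe": summary.median_theta,
            "mean_sspe": summary.mean_theta,
            "n_used": summary.n_used,
            "n_flagged": summary.n_flagged,
        }
        if "design" in state and config.n_sim_validation >= 2:
            lo, hi = median_sspe_interval(
                state["model"],
                state["design"],
                n_sim=config.n_sim_validation,
                seed=_derive(rng_seeds[2]),
            )
            result["median_sspe_interval_95"] = [lo, hi]
        with open(out / "cv_summary.json", "w") as fh:
            json.dump(result, fh, indent=2)

    @stage("tables")
    def _tables():
        thresholds = ThresholdSet(dict(config.thresholds))
        groups = summarize_groups(state["table"], ["group"])
        groups.to_csv(out / "group_summaries.csv", index=False)
        prev = prevalence_below(state["table"], thresholds, strata=["group"])
        prev.to_csv(out / "prevalence.csv", index=False)
        (out / "tables.txt").write_text(
            render_table(groups) + "\n\n" + render_table(prev) + "\n"
        )

    _write_manifest(out, manifest)
    return manifest


def _derive(ss: np.random.SeedSequence) -> int:
    return int(ss.generate_state(1)[0] % (2**31))


def _write_manifest(out: Path, manifest: dict) -> None:
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2)
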