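"""End-to-end orchestration: data -> decomposition -> design -> fit -> assessment.

One configuration object drives a per-species run: generate (or ingest) the
climate cubes, route panel and counts; decompose both climate variables;
assemble the design; select the error family and climate covariate blocks by
AIC; screen the fit against the per-country/pooled Pearson thresholds; and
when the screen passes, build the component effect grids, correlate them and
classify the species' response.  Every stage result is recorded in a JSON
manifest and the run is a pure function of (inputs, config, seed).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import synthetic_data as synth
from .decomposition import ClimateCube, decompose
from .covariates import DesignSpec, assemble_design
from .abundance import FittedModel, ModelSpec, fit, select_family, select_covariates
from .assessment import (
    COMPONENTS,
    build_component_grid,
    classify_species,
    correlate_components,
    performance_pearson,
)

__all__ = ["RunConfig", "run_pipeline", "save_model", "load_model"]

log = logging.getLogger("climdecomp")


@dataclass
class RunConfig:
    """Configuration of a full pipeline run (YAML-loadable)."""

    mode: str = "synthetic"                  # synthetic | ingest
    synthetic: dict = field(default_factory=dict)
    true_params: dict = field(default_factory=dict)
    inputs: dict = field(default_factory=dict)   # ingest-mode file paths
    season_window: str = "may-jul"
    lag: int = 0
    centering_years: tuple[int, int] = (1971, 2018)
    study_years: tuple[int, int] = (1996, 2018)
    family: str = "auto"                     # auto = AIC among all four
    select_blocks: bool = True
    quad_order: int = 7
    habitat: tuple[str, ...] = (
        "mountain_vegetation", "other_forest", "wetlands", "slope",
    )
    grid_levels: int = 10
    classification_threshold: float = 0.5
    country_threshold: float = 0.4
    pooled_threshold: float = 0.5
    outdir: str = "runs/latest"
    seed: int = 20180531
    log_level: str = "INFO"

    def __post_init__(self) -> None:
        if self.mode not in ("synthetic", "ingest"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.lag not in (0, 1):
            raise ValueError("lag must be 0 or 1")
        for t in (self.classification_threshold, self.country_threshold,
                  self.pooled_threshold):
            if not 0 <= t <= 1:
                raise ValueError("thresholds must be in [0, 1]")
        if self.mode == "ingest":
            for key in ("temperature", "precipitation", "routes", "counts"):
                path = self.inputs.get(key)
                if path is None or not Path(path).exists():
                    raise FileNotFoundError(f"ingest input {key!r} missing: {path}")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        for key in ("centering_years", "study_years", "habitat"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return cls(**raw)


def save_model(model: FittedModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2))


def load_model(path: str | Path) -> FittedModel:
    return FittedModel.from_dict(json.loads(Path(path).read_text()))


def _load_data(config: RunConfig):
    """Either generate the synthetic dataset or read the ingest files."""
    if config.mode == "synthetic":
        scfg = synth.SyntheticConfig(
            centering_years=config.centering_years,
            study_years=config.study_years,
            seed=config.seed,
            **config.synthetic,
        )
        cubes = {
            v: synth.generate_climate(scfg, v)
            for v in ("temperature", "precipitation")
        }
        routes = synth.generate_routes(scfg)
        habitat = synth.generate_habitat_covariates(scfg, routes)
        params = (
            synth.TrueParameters(**config.true_params)
            if config.true_params else synth.TrueParameters.default()
        )
        dec = {v: decompose(cubes[v], config.study_years) for v in cubes}
        counts, _ = synth.generate_counts(
            routes, dec["temperature"], dec["precipitation"], params,
            covariates=habitat, lag=config.lag, seed=scfg.seed,
        )
        return cubes, routes, habitat, counts, params
    cubes = {
        v: ClimateCube.from_csv(
            config.inputs[v], variable=v,
            centering_years=config.centering_years,
            season_window=config.season_window,
        )
        for v in ("temperature", "precipitation")
    }
    routes = pd.read_csv(config.inputs["routes"])
    habitat = (
        pd.read_csv(config.inputs["habitat"])
        if config.inputs.get("habitat") else None
    )
    counts = pd.read_csv(config.inputs["counts"])
    return cubes, routes, habitat, counts, None


def run_pipeline(config: RunConfig) -> dict:
    """Execute every stage and return (and write) the run manifest."""
    logging.basicConfig(level=config.log_level)
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {
            k: (list(v) if isinstance(v, tuple) else v)
            for k, v in asdict(config).items()
        },
        "stages": {},
    }

    def _record(stage: str, **info) -> None:
        manifest["stages"][stage] = info
        log.info("stage %s: %s", stage, info)

    try:
        cubes, routes, habitat, counts, params = _load_data(config)
        _record(
            "data", n_routes=int(routes["route_id"].nunique()),
            n_route_years=int(len(routes)), n_count_rows=int(len(counts)),
        )

        dec = {v: decompose(cubes[v], config.study_years) for v in cubes}
        for v, d in dec.items():
            d.write(outdir, prefix=v)
        _record(
            "decompose",
            global_mean={v: d.global_mean for v, d in dec.items()},
            lag=config.lag,
        )

        design = assemble_design(
            routes, habitat, dec["temperature"], dec["precipitation"],
            lag=config.lag, spec=DesignSpec(habitat=config.habitat),
            counts=counts,
        )
        _record(
            "design", n_rows=len(design.X), n_terms=len(design.X.columns),
            dropped_for_lag=design.n_dropped_lag,
        )

        base = ModelSpec(quad_order=config.quad_order)
        if config.family == "auto":
            fam_sel = select_family(design, base)
            fam_sel.table.to_csv(outdir / "family_aic.csv", index=False)
            model = fam_sel.best
            _record(
                "family", selected=model.spec.family,
                table=fam_sel.table.to_dict("records"),
            )
        else:
            model = fit(design, ModelSpec(
                family=config.family, quad_order=config.quad_order,
            ))
            _record("family", selected=config.family, forced=True)

        retained = None
        if config.select_blocks:
            cov_sel = select_covariates(design, base_spec=model.spec)
            cov_sel.table.to_csv(outdir / "block_selection.csv", index=False)
            model = cov_sel.best
            retained = cov_sel.retained
            _record("blocks", retained=retained)
        if not model.converged:
            raise RuntimeError("final model did not converge")
        save_model(model, outdir / "model.json")

        perf = performance_pearson(
            model, design,
            country_threshold=config.country_threshold,
            pooled_threshold=config.pooled_threshold,
        )
        perf.per_group.to_csv(outdir / "performance.csv", index=False)
        _record(
            "performance", pooled_r=perf.pooled_r, passed=bool(perf.passed),
            per_group=perf.per_group.to_dict("records"),
        )
        if not perf.passed:
            manifest["assessed"] = False
            manifest["status"] = "screened-out"
            (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
            return manifest

        grids = {
            c: build_component_grid(
                model, design, dec["temperature"], dec["precipitation"], c,
                n_levels=config.grid_levels, retained=retained,
            )
            for c in COMPONENTS
        }
        pd.concat([g.to_frame() for g in grids.values()]).to_csv(
            outdir / "effect_grids.csv", index=False,
        )
        summary = correlate_components(grids)
        summary.table.to_csv(outdir / "component_correlations.csv", index=False)
        cls = classify_species(
            summary, grids["spatial"], threshold=config.classification_threshold,
        )
        _record(
            "assessment", classification=cls.combined,
            r_spatial_temporal_temp=cls.r_spatial_temporal_temp,
        )
        manifest["assessed"] = True
        manifest["status"] = "ok"
    except Exception as err:
        manifest["status"] = "failed"
        manifest["error"] = f"{type(err).__name__}: {err}"
        (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
        raise
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return manifest
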