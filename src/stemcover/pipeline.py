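"""End-to-end pipeline: simulate -> pseudo-lists -> STEM -> coverage -> stats."""

from __future__ import annotations

import json
import logging
import time
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .config import PipelineConfig
from .coverage import coverage_table, species_means
from .io import (
    write_checklists,
    write_predictions,
    write_protected_layer,
    write_world,
)
from .pseudolists import fit_list_length_model, merge_lists, promote_casual_records
from .stats import fit_coverage_lmm, fit_trend_lm, habitat_contrasts
from .stem import (
    Extent,
    build_partitions,
    cross_validate,
    fit_base_models,
    predict_occurrence,
    week_of_day,
)
from .world import (
    EffortConfig,
    Phenology,
    make_protected_layer,
    make_world,
    simulate_effort,
    simulate_species,
)

log = logging.getLogger("stemcover")


def _species_phenologies(n_species: int, rng: np.random.Generator) -> list[Phenology]:
    """Distinct but realistic trans-Saharan phenologies per simulated species."""
    out = []
    for _ in range(n_species):
        arrival = int(rng.integers(65, 95))
        out.append(
            Phenology(
                arrival_day=arrival,
                breeding_start=arrival + int(rng.integers(50, 70)),
                breeding_end=arrival + int(rng.integers(130, 160)),
                departure_day=arrival + int(rng.integers(195, 220)),
                breeding_lat_frac=float(rng.uniform(0.55, 0.85)),
                spread_km=float(rng.uniform(140, 220)),
            )
        )
    return out


def run_pipeline(config: PipelineConfig, run_cv: bool = True) -> Path:
    """Execute every stage and write artifacts + manifest to ``out_dir``.

    Stages: synthetic world & effort, list-length model & promotion, STEM
    fit & weekly prediction, coverage table, association models.  Rerunning
    with an identical config is bit-identical for every deterministic
    stage.  Returns the run directory.
    """
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    stage = "init"
    manifest: dict = {"version": __version__, "config": config.to_dict(), "stages": {}}

    try:
        stage = "simulate"
        wc = config.world
        world = make_world(wc.n_x, wc.n_y, wc.cell_size_km, seed=wc.seed)
        layer = make_protected_layer(
            world, wc.protected_total_fraction,
            farmland_bias=wc.protected_farmland_bias, seed=wc.seed + 1,
        )
        rng = np.random.default_rng(config.seed)
        phenologies = _species_phenologies(wc.n_species, rng)
        species_ids = [f"SP{i + 1}" for i in range(wc.n_species)]
        occupancies = []
        for sp, ph in zip(species_ids, phenologies):
            beta_trees = float(rng.uniform(6.0, 9.0))
            occupancies.append(
                simulate_species(
                    world, ph,
                    covariate_effects={"trees": beta_trees, "crops": -4.0},
                    species_id=sp, seed=config.seed,
                )
            )
        eff = EffortConfig(
            events_per_cell_day=config.effort.events_per_cell_day,
            p_complete=config.effort.p_complete,
            detectability=config.effort.detectability,
            casual_rate=config.effort.casual_rate,
            casual_report_rate=config.effort.casual_report_rate,
            habitat_bias=dict(config.effort.habitat_bias),
        )
        checklists = simulate_effort(world, occupancies, eff, seed=config.seed + 2)
        write_world(world, out / "world.csv")
        write_protected_layer(layer, out / "protected.csv")
        write_checklists(checklists, out / "checklists.csv")
        manifest["stages"]["simulate"] = {
            "n_cells": world.n_cells, "n_checklists": len(checklists),
            "species": species_ids,
        }

        stage = "pseudolists"
        complete = checklists[checklists["type"] == "complete"]
        casual = checklists[checklists["type"] == "casual"]
        llm = fit_list_length_model(complete, world, seed=config.seed + 3)
        pseudo = promote_casual_records(casual, llm)
        merged = merge_lists(complete, pseudo)
        write_checklists(merged, out / "merged_lists.csv")
        manifest["stages"]["pseudolists"] = {
            "n_complete": len(complete),
            "n_casual_cell_days": int(casual.groupby(["cell_id", "date"]).ngroups),
            "n_pseudo": len(pseudo),
            "r2_in_sample": llm.r2_in_sample,
        }

        stage = "fit-stem"
        sc = config.stem
        extent = Extent.from_world(world)
        partitions = build_partitions(
            extent, width_km=sc.width_km, depth_days=sc.depth_days,
            n_partitions=sc.n_partitions, seed=config.seed + 4,
        )
        all_preds = []
        cv_results = {}
        for sp, occ in zip(species_ids, occupancies):
            ens = fit_base_models(
                merged, world, partitions, sp,
                min_lists=sc.min_lists, gbm=sc.gbm, seed=config.seed + 5,
                floor=sc.floor,
            )
            w0 = week_of_day(occ.arrival_day)
            w1 = week_of_day(occ.departure_day)
            for week in range(w0, w1 + 1):
                all_preds.append(predict_occurrence(ens, week))
            if run_cv:
                cv_results[sp] = cross_validate(
                    merged, world, partitions, sp, k=sc.cv_folds,
                    seed=config.seed + 6, min_lists=sc.min_lists, gbm=sc.gbm,
                    floor=sc.floor,
                )
        preds = pd.concat(all_preds, ignore_index=True)
        write_predictions(preds, out / "predictions.csv")
        manifest["stages"]["stem"] = {
            "n_partitions": sc.n_partitions,
            "cv": {sp: r["mean_auc"] for sp, r in cv_results.items()},
        }

        stage = "coverage"
        cov = coverage_table(
            preds, layer, cell_area_km2=world.cell_area_km2,
            cutoff=config.coverage.season_cutoff,
            target_bases=config.coverage.target_bases,
        )
        cov.to_csv(out / "coverage.csv", index=False)
        manifest["stages"]["coverage"] = {"n_rows": len(cov)}

        stage = "stats"
        stats_out: dict = {}
        if cov["species_id"].nunique() >= 2 and cov["season"].nunique() >= 2:
            stats_out["coverage_lmm"] = fit_coverage_lmm(cov).to_dict()
        # Habitat / trend models need species metadata; synthesise labels from
        # the simulated covariate affinities (all tree-associated -> forest).
        sm = species_means(cov)
        if len(sm) >= 10:
            meta = sm.assign(trend_pct=0.0, habitat="forest", migration="long")
            stats_out["trend_lm"] = fit_trend_lm(meta).to_dict()
        (out / "fits.json").write_text(json.dumps(stats_out, indent=2, default=str))
        manifest["stages"]["stats"] = {"models": sorted(stats_out)}
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r} (artifacts in {out})") from exc

    manifest["runtime_s"] = round(time.time() - t0, 2)
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    return out
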