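"""End-to-end pipeline driver.

Chains the analysis stages — synthetic-world generation (or loading of
prepared inputs), occurrence QC, distribution modelling with buffer
fallback, future ensembles and climate-stable ranges, ELC zonation, gap
analysis, reserve selection and greedy site prioritization — writing each
stage's tables to an output directory together with a manifest of every
parameter and seed used.  All randomness flows from one root seed through
named per-stage substreams, so a rerun with the same configuration is
byte-reproducible.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path

import zlib

import numpy as np
import pandas as pd
import yaml

from . import elc as elc_mod
from . import gap_analysis as gap
from . import occurrence_qc as qc
from . import prioritization as prio
from . import reserve_selection as rs
from . import sdm
from .grids import VARIABLE_SETS, GridSpec
from .io import write_json
from .synthetic_landscape import LandscapeConfig, SyntheticWorld, generate_world

_STAGE_STREAMS = {"simulate": 1, "sdm": 2, "elc": 3, "select": 4}


@dataclass
class PipelineConfig:
    """Every tunable parameter of the pipeline, with field defaults.

    The analysis defaults (10-km uncertainty cut, 10-record modelling
    minimum, 10,000 background points, 5 CV folds, VIF threshold 10,
    50-km buffers, unit costs 10/50, SPF 1, BLM 0.001, 100 annealing
    runs, 100 + 50 top sites) are the configuration of the global
    assessment this package models; the synthetic-world and iteration
    sizes are desk-scale.
    """

    seed: int = 0
    # synthetic world
    grid_rows: int = 60
    grid_cols: int = 60
    cell_size_km: float = 5.0
    n_species: int = 20
    n_occurrences: int = 400
    n_future_realizations: int = 5
    autocorr_length_km: float = 50.0
    pa_target_fraction: float = 0.15
    # occurrence QC
    max_uncertainty_km: float = 10.0
    min_records_for_model: int = 10
    # distribution modelling
    n_background: int = 10_000
    cv_folds: int = 5
    vif_threshold: float = 10.0
    regularization: float = 0.05
    min_mean_auc: float = 0.7
    max_auc_sd: float = 0.15
    buffer_radius_km: float = 50.0
    # ELC
    k_per_set: int = 3
    # reserve selection
    cost_pa: float = 10.0
    cost_out: float = 50.0
    spf: float = 1.0
    blm: float = 0.001
    n_runs: int = 10
    n_iterations: int = 20_000
    lock_in_pa: bool = False
    # prioritization
    top_pa: int = 100
    top_out: int = 50

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def manifest(self) -> dict:
        return dataclasses.asdict(self)


@dataclass
class SpeciesResult:
    species_id: str
    pathway: str  # model | buffer | excluded
    n_unique_records: int
    current: sdm.RangeMap | None = None
    future: sdm.RangeMap | None = None
    stable: sdm.RangeMap | None = None
    loss: float | None = None
    threshold: float | None = None
    fold_aucs: list[float] | None = None
    retained_variables: list[str] | None = None
    elc: elc_mod.ELCMap | None = None
    model: sdm.NicheModel | None = None
    suitability: np.ndarray | None = None  # continuous baseline projection

    @property
    def planning_mask(self) -> np.ndarray | None:
        """Range used in reserve selection: climate-stable when a valid
        future model exists and retains area, otherwise current."""
        if self.stable is not None and self.stable.n_cells > 0:
            return self.stable.mask
        return self.current.mask if self.current is not None else None


def _sid_key(sid: str) -> int:
    return zlib.crc32(sid.encode()) % 2**16


def _stage_seed(root: int, stage: str, extra: int = 0) -> int:
    rng = np.random.default_rng([root, _STAGE_STREAMS[stage], extra])
    return int(rng.integers(2**31))


def model_species(
    sid: str,
    occ_xy: np.ndarray,
    world: SyntheticWorld,
    config: PipelineConfig,
    pathway: str,
) -> SpeciesResult:
    """Run the modelling chain for one cleaned species."""
    env = world.env
    grid = env.grid
    native = world.native_range[sid]
    result = SpeciesResult(species_id=sid, pathway=pathway, n_unique_records=len(occ_xy))
    if pathway == "excluded":
        return result

    if pathway == "model":
        sp_seed = _stage_seed(config.seed, "sdm", _sid_key(sid))
        bg_cells = sdm.sample_background(grid, native, config.n_background, seed=sp_seed)
        bg_mask = np.zeros(grid.n_cells, dtype=bool)
        bg_mask[bg_cells] = True
        bg_mask = bg_mask.reshape(grid.shape)
        screen = sdm.screen_vif(
            env.values(mask=bg_mask), env.variables, threshold=config.vif_threshold
        )
        retained = screen.retained
        # ELC needs every set represented; put back a set's first variable
        # if screening emptied it
        for s in VARIABLE_SETS:
            if not any(env.sets[v] == s for v in retained):
                retained.append(env.variables_in_set(s)[0])
        result.retained_variables = retained
        row, col = grid.xy_to_rowcol(occ_xy[:, 0], occ_xy[:, 1])
        pres_vals = np.column_stack([env.layers[v][row, col] for v in retained])
        bg_vals = env.values(retained, mask=bg_mask)
        Fp, fnames = sdm.make_features(pres_vals, retained)
        Fb, _ = sdm.make_features(bg_vals, retained)
        aucs, adequate = sdm.crossvalidate(
            Fp,
            Fb,
            k=config.cv_folds,
            seed=sp_seed,
            regularization=config.regularization,
            min_mean_auc=config.min_mean_auc,
            max_auc_sd=config.max_auc_sd,
        )
        result.fold_aucs = [float(a) for a in aucs]
        if adequate:
            model = sdm.fit_presence_background(
                Fp, Fb, feature_names=fnames, regularization=config.regularization, species_id=sid
            )
            thr = sdm.maxtrss_threshold(model.suitability(Fp), model.suitability(Fb))
            result.threshold = thr.threshold
            suit = sdm.project(model, env, retained)
            result.model = model
            result.suitability = suit
            result.current = sdm.binarize(suit, thr.threshold, native, species_id=sid)
            if world.futures:
                result.future = sdm.future_ensemble(
                    model, world.futures, thr.threshold, native, retained
                )
                if result.current.n_cells > 0:
                    result.stable, result.loss = sdm.stable_range(result.current, result.future)
            if result.current.n_cells > 0:
                return result
        # inadequate or degenerate model: fall through to the buffer pathway
        result.pathway = "buffer"
        result.future = result.stable = None
        result.loss = result.threshold = None

    result.current = sdm.buffer_range(
        occ_xy, grid, radius_km=config.buffer_radius_km, native_range=native, species_id=sid
    )
    return result


def run_pipeline(
    config: PipelineConfig,
    out_dir: str | Path,
    world: SyntheticWorld | None = None,
) -> dict:
    """Execute the full pipeline and write all artifacts to ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    # --- simulate -----------------------------------------------------
    if world is None:
        lc = LandscapeConfig(
            grid=GridSpec(config.grid_rows, config.grid_cols, config.cell_size_km),
            autocorr_length_km=config.autocorr_length_km,
            seed=_stage_seed(config.seed, "simulate"),
            n_future_realizations=config.n_future_realizations,
        )
        world = generate_world(
            lc,
            n_species=config.n_species,
            n_occurrences=config.n_occurrences,
            pa_target_fraction=config.pa_target_fraction,
        )
    grid = world.env.grid
    world.occurrences.to_csv(out / "occurrences.csv", index=False)
    world.truth.to_csv(out / "truth.csv", index=False)

    # --- occurrence QC ------------------------------------------------
    clean_df, report = qc.clean(
        world.occurrences,
        world.native_range,
        grid,
        max_uncertainty_km=config.max_uncertainty_km,
        min_records_for_model=config.min_records_for_model,
    )
    report.to_csv(out / "qc_report.csv", index=False)

    # --- SDM + ELC per species ---------------------------------------
    results: dict[str, SpeciesResult] = {}
    for _, rep in report.iterrows():
        sid = rep["species_id"]
        occ_xy = clean_df.loc[clean_df["species_id"] == sid, ["x_km", "y_km"]].to_numpy()
        res = model_species(sid, occ_xy, world, config, rep["pathway"])
        if res.pathway != "excluded":
            retained = res.retained_variables or world.env.variables
            by_set = {s: [v for v in retained if world.env.sets[v] == s] for s in VARIABLE_SETS}
            res.elc = elc_mod.build_elc(
                world.env,
                by_set,
                k_per_set=config.k_per_set,
                native_range=world.native_range[sid],
                seed=_stage_seed(config.seed, "elc", _sid_key(sid)),
                species_id=sid,
            )
        results[sid] = res

    cards = pd.DataFrame(
        [
            {
                "species_id": r.species_id,
                "pathway": r.pathway,
                "n_unique_records": r.n_unique_records,
                "threshold": r.threshold,
                "mean_auc": float(np.mean(r.fold_aucs)) if r.fold_aucs else None,
                "current_cells": r.current.n_cells if r.current else 0,
                "stable_cells": r.stable.n_cells if r.stable else None,
                "loss": r.loss,
            }
            for r in results.values()
        ]
    )
    cards.to_csv(out / "model_cards.csv", index=False)

    # --- gap analysis -------------------------------------------------
    crop_by_sp = world.crop_map.groupby("species_id")["crop"].apply(list)
    gap_records = []
    for sid, r in results.items():
        if r.current is None:
            continue
        gap_records.append(
            gap.species_gap_record(
                species_id=sid,
                crops=crop_by_sp.get(sid, []),
                n_occurrences=r.n_unique_records,
                pathway=r.pathway,
                current_mask=r.current.mask,
                pa_mask=world.pa_mask,
                elc=r.elc,
                stable_mask=r.stable.mask if r.stable is not None else None,
                range_loss=r.loss,
            )
        )
    gap_df = gap.records_to_frame(gap_records)
    gap_df.to_csv(out / "gap_records.csv", index=False)
    crop_summary = gap.summarize_by_crop_type(gap_df, world.crop_map)
    crop_summary.to_csv(out / "crop_type_summary.csv", index=False)

    # --- reserve selection -------------------------------------------
    planning_masks = {
        sid: r.planning_mask for sid, r in results.items() if r.planning_mask is not None
    }
    elc_maps = {sid: results[sid].elc for sid in planning_masks}
    problem = rs.build_problem(
        planning_masks,
        elc_maps,
        world.pa_mask,
        grid,
        cost_pa=config.cost_pa,
        cost_out=config.cost_out,
        spf=config.spf,
        blm=config.blm,
        lock_in_pa=config.lock_in_pa,
    )
    ensemble = rs.anneal(
        problem,
        n_runs=config.n_runs,
        n_iterations=config.n_iterations,
        seed=_stage_seed(config.seed, "select"),
    )
    best = ensemble.best
    pd.DataFrame(
        [
            {
                "run_index": s.run_index,
                "n_units": s.n_units,
                "cost": s.cost,
                "boundary": s.boundary,
                "penalty": s.penalty,
                "objective": s.objective,
            }
            for s in ensemble.solutions
        ]
    ).to_csv(out / "annealing_runs.csv", index=False)

    # --- prioritization ----------------------------------------------
    sel = best.selected_units
    unit_combos = {
        int(u): {problem.combo_keys[c] for c in problem.unit_combos[u]} for u in sel
    }
    pa_flags = {int(u): bool(world.pa_mask.ravel()[problem.unit_cells[u]]) for u in sel}
    ranking = prio.greedy_rank(sorted(unit_combos), unit_combos, pa_flags, mode="pragmatic")
    ranking.table.to_csv(out / "site_ranking.csv", index=False)
    top = prio.top_sites(ranking, n_pa=config.top_pa, n_out=config.top_out)
    top.to_csv(out / "top_sites.csv", index=False)
    n_assessed = int((report["pathway"] != "excluded").sum())
    stats = prio.headline_stats(top, unit_combos, n_assessed, max(problem.n_combos, 1))

    summary = {
        "n_species": len(results),
        "n_assessed": n_assessed,
        "n_model": int((cards["pathway"] == "model").sum()),
        "n_buffer": int((cards["pathway"] == "buffer").sum()),
        "n_excluded": int((cards["pathway"] == "excluded").sum()),
        "n_combos": problem.n_combos,
        "n_planning_units": problem.n_units,
        "best_run": best.run_index,
        "best_n_units": best.n_units,
        "best_cost": best.cost,
        "best_objective": best.objective,
        "n_sites_ranked": len(ranking.table),
        "top_sites": stats,
    }
    write_json(out / "summary.json", summary)
    write_json(out / "manifest.json", {"config": config.manifest(), "stages": list(_STAGE_STREAMS)})
    return {
        "world": world,
        "qc_report": report,
        "results": results,
        "gap_records": gap_df,
        "crop_summary": crop_summary,
        "problem": problem,
        "ensemble": ensemble,
        "ranking": ranking,
        "top_sites": top,
        "summary": summary,
    }
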