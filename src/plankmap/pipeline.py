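"""End-to-end orchestration: simulate/ingest -> rarefy -> per-group SOM ->
geographic labeling -> diversity -> environmental summaries -> driver ranking
-> slope-proportion coupling, written out as TSV tables plus a JSON manifest.

One master seed drives every stochastic stage through named SeedSequence
children, so reruns with the same config and seed are byte-identical.  A
failure in one taxonomic group's SOM is recorded and does not abort the other
groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from plankmap.core_data import Dataset, read_tables, write_results, write_tables
from plankmap.diversity import alpha_summary, diversity_table, gamma_per_station, phase_similarity
from plankmap.geo_env import (cruise_slope_table, label_clusters, nearshore_frequency,
                              proportion_nearshore)
from plankmap.models import fit_glm, fit_line_by_phase, rank_predictors
from plankmap.preprocess import rarefy, relative_abundance, station_summaries, subset_group
from plankmap.som import SomConfig, classify_samples, cluster_neurons, train_som
from plankmap.synthetic import SimConfig, simulate_dataset

log = logging.getLogger("plankmap.pipeline")

ENV_VARIABLES = ("temperature", "salinity", "no3", "po4", "sio4", "chl_a", "ncd")


@dataclass
class RunConfig:
    """Everything a reproducible run needs."""

    out_dir: str | Path = "plankmap_run"
    input_dir: str | Path | None = None      # None -> simulate a dataset
    sim: SimConfig = field(default_factory=SimConfig)
    rarefaction_depth: int = 17_000
    groups: tuple[str, ...] | None = None    # None -> all configured groups
    som_grid: tuple[int, int] = (6, 6)
    som: SomConfig = field(default_factory=SomConfig)
    min_station_samples: int = 4             # GLM station filter (one year of data)
    phase_a: str = "warm"
    phase_b: str = "cool"
    seed: int = 0
    write_dataset: bool = False


@dataclass
class PipelineResult:
    dataset: Dataset
    tables: dict[str, pd.DataFrame]
    models: dict[str, object]
    classifications: pd.DataFrame
    failures: dict[str, str]
    manifest_path: Path | None


def _community_drivers(freq: pd.DataFrame, summaries: pd.DataFrame,
                       min_trials: int) -> dict:
    """Binomial fits of nearshore frequency on each mean/CV predictor."""
    merged = freq.merge(summaries, on="station_id")
    merged = merged[merged["trials"] >= min_trials]
    fits = {}
    for var in ENV_VARIABLES:
        for stat in ("mean", "cv"):
            colname = f"{var}_{stat}"
            sub = merged.dropna(subset=[colname])
            if len(sub) < 3:
                continue
            fits[colname] = fit_glm(sub[colname].to_numpy(),
                                    sub["successes"].to_numpy(),
                                    family="binomial",
                                    trials=sub["trials"].to_numpy())
    return fits


def _diversity_drivers(alpha: pd.DataFrame, summaries: pd.DataFrame,
                       min_samples: int) -> dict:
    """Gaussian fits of station mean alpha diversity on each predictor."""
    merged = alpha.merge(summaries, on="station_id")
    merged = merged[merged["n_samples"] >= min_samples]
    fits = {}
    for var in ENV_VARIABLES:
        for stat in ("mean", "cv"):
            colname = f"{var}_{stat}"
            sub = merged.dropna(subset=[colname])
            if len(sub) < 3:
                continue
            fits[colname] = fit_glm(sub[colname].to_numpy(),
                                    sub["mean_alpha"].to_numpy(),
                                    family="gaussian")
    return fits


def run_pipeline(config: RunConfig) -> PipelineResult:
    """Execute all stages and write the result bundle under ``config.out_dir``."""
    rng_children = np.random.SeedSequence(config.seed).spawn(2)
    rarefy_rng = np.random.default_rng(rng_children[0])

    # --- ingest or simulate -------------------------------------------------
    if config.input_dir is not None:
        dataset = read_tables(config.input_dir)
        log.info("ingested %d samples, %d ASVs", dataset.asv.n_samples,
                 dataset.asv.n_asvs)
    else:
        dataset = simulate_dataset(config.sim, seed=config.seed)
        log.info("simulated %d samples, %d ASVs", dataset.asv.n_samples,
                 dataset.asv.n_asvs)

    # --- rarefaction --------------------------------------------------------
    rarefied, rare_report = rarefy(dataset.asv, config.rarefaction_depth, rarefy_rng)
    kept = set(rarefied.sample_ids)
    samples = dataset.samples[dataset.samples["sample_id"].isin(kept)].reset_index(drop=True)
    log.info("rarefied to %d reads: %d kept, %d dropped", rare_report.depth,
             len(rare_report.kept), len(rare_report.dropped))

    groups = tuple(config.groups or dataset.taxonomy.group_names)
    som_seeds = {g: int(np.random.SeedSequence([config.seed, 7, i]).generate_state(1)[0]
                        % (2 ** 31)) for i, g in enumerate(groups)}

    # --- per-group SOM classification --------------------------------------
    failures: dict[str, str] = {}
    models: dict[str, object] = {}
    class_frames, geo_frames = [], []
    for group in groups:
        try:
            sub, zero_samples = subset_group(rarefied, dataset.taxonomy, group)
            usable = [s for s in sub.sample_ids if s not in set(zero_samples)]
            sub = sub.select_samples(usable)
            props = relative_abundance(sub).to_numpy().T  # samples x ASVs
            model = train_som(props, grid=config.som_grid, config=config.som,
                              seed=som_seeds[group])
            cluster_neurons(model, k=2)
            cls = classify_samples(model, props, sample_ids=sub.sample_ids, group=group)
            geo = label_clusters(cls, samples, dataset.stations)
            geo.insert(0, "group", group)
            model.cluster_labels = dict(zip(geo["cluster"], geo["label"]))
            models[group] = model
            class_frames.append(cls)
            geo_frames.append(geo)
            log.info("group %s: SOM trained, clusters labeled", group)
        except Exception as exc:  # stage isolation: one group must not kill the rest
            failures[group] = f"{type(exc).__name__}: {exc}"
            log.error("group %s failed: %s", group, failures[group])
    if not class_frames:
        raise RuntimeError(f"every group failed: {failures}")
    classifications = pd.concat(class_frames, ignore_index=True)
    geography = pd.concat(geo_frames, ignore_index=True)

    # --- diversity ----------------------------------------------------------
    div = diversity_table(rarefied, samples, group="all")
    alpha_station = alpha_summary(div, by="station")
    alpha_cruise = alpha_summary(div, by="cruise")
    gamma = gamma_per_station(rarefied, samples)
    diversity_out = (alpha_station.merge(gamma, on="station_id", how="outer")
                     .rename(columns={"n_samples": "n_samples_station"}))

    sim_frames = []
    for group in groups:
        if group in failures:
            continue
        try:
            sims, _rep = phase_similarity(rarefied, samples, dataset.taxonomy,
                                          group=group, phase_a=config.phase_a,
                                          phase_b=config.phase_b)
            sim_frames.append(sims)
        except Exception as exc:
            failures[f"phase_similarity:{group}"] = f"{type(exc).__name__}: {exc}"
    phase_sim = (pd.concat(sim_frames, ignore_index=True) if sim_frames
                 else pd.DataFrame())

    # --- environment --------------------------------------------------------
    summaries = station_summaries(dataset.profiles)
    slopes = cruise_slope_table(dataset.profiles, dataset.stations)

    # --- driver ranking -----------------------------------------------------
    driver_frames = []
    for group in groups:
        if group in failures:
            continue
        cls = classifications[classifications["group"] == group]
        freq = nearshore_frequency(cls, samples)
        try:
            fits = _community_drivers(freq, summaries, config.min_station_samples)
            ranked = rank_predictors(fits, response=f"{group}:nearshore-frequency")
            ranked.insert(0, "group", group)
            driver_frames.append(ranked)
        except Exception as exc:
            failures[f"drivers:{group}"] = f"{type(exc).__name__}: {exc}"
    try:
        fits = _diversity_drivers(alpha_station, summaries, config.min_station_samples)
        ranked = rank_predictors(fits, response="all:mean-alpha")
        ranked.insert(0, "group", "all")
        driver_frames.append(ranked)
    except Exception as exc:
        failures["drivers:diversity"] = f"{type(exc).__name__}: {exc}"
    drivers = (pd.concat(driver_frames, ignore_index=True) if driver_frames
               else pd.DataFrame())

    # --- slope-proportion coupling ------------------------------------------
    cruise_phase = samples.drop_duplicates("cruise_id")[["cruise_id", "phase"]]
    coupling_frames = []
    for group in groups:
        if group in failures:
            continue
        cls = classifications[classifications["group"] == group]
        prop = proportion_nearshore(cls, samples)
        joined = (prop.merge(slopes[["cruise_id", "slope_m_per_km"]], on="cruise_id")
                  .merge(cruise_phase, on="cruise_id").dropna(subset=["slope_m_per_km"]))
        fits, skipped = fit_line_by_phase(joined["slope_m_per_km"].to_numpy(),
                                          joined["proportion_nearshore"].to_numpy(),
                                          joined["phase"].to_numpy())
        fits.insert(0, "group", group)
        if skipped:
            failures.setdefault(f"coupling:{group}",
                                f"phases skipped (<3 cruises): {skipped}")
        coupling_frames.append(fits)
    coupling = (pd.concat(coupling_frames, ignore_index=True) if coupling_frames
                else pd.DataFrame())

    tables = {
        "geography": geography,
        "classifications": classifications,
        "diversity": diversity_out,
        "alpha_by_cruise": alpha_cruise,
        "phase_similarity": phase_sim,
        "station_summaries": summaries,
        "slopes": slopes,
        "drivers": drivers,
        "slope_coupling": coupling,
    }

    manifest_path = None
    if config.out_dir is not None:
        out_dir = Path(config.out_dir)
        if config.write_dataset:
            write_tables(dataset, out_dir / "dataset")
        manifest_path = write_results(
            tables, out_dir, seed=config.seed,
            config={"rarefaction_depth": config.rarefaction_depth,
                    "som_grid": list(config.som_grid),
                    "groups": list(groups),
                    "min_station_samples": config.min_station_samples,
                    "sim": config.sim.to_dict() if config.input_dir is None else None},
            extra_manifest={
                "rarefaction": {"depth": rare_report.depth,
                                "n_kept": len(rare_report.kept),
                                "dropped": rare_report.dropped},
                "failures": failures,
            })
        for group, model in models.items():
            model.to_json(out_dir / f"som_{group}.json")
    return PipelineResult(dataset=dataset, tables=tables, models=models,
                          classifications=classifications, failures=failures,
                          manifest_path=manifest_path)
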