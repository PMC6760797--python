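"""End-to-end pipeline: observations → fits → phenology → life tables → maps.

Every run writes a self-describing artifact directory: the selected
parameter sets as JSON, a life-table report CSV, optional index rasters
per warming scenario, a log, and a manifest with the configuration,
seeds, input hashes and package version, sufficient to reproduce the run.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path
import numpy as np
import pandas as pd

from . import __version__
from . import observations as obs_io
from . import thermal_models as tm
from .config import RunConfig
from .fitting import (FitError, fit_linear_dd, fit_nonlinear,
                      mortality_from_observations, rates_from_times,
                      select_model)
from .life_table import build_phenology, replicate_simulation
from .spatial import (apply_scenario_offset, grid_from_directory, map_indices,
                      write_index_rasters)

logger = logging.getLogger("phenotherm")

__all__ = ["fit_all", "run_pipeline", "estimate_sigmas"]


def _sha256(path) -> str:
    return hashlib.sha256(Path(path).read_bytes()).hexdigest()


def estimate_sigmas(stage_obs: dict) -> dict:
    """Pooled lognormal sigma of individual development times per stage.

    Within each temperature, completers' log-durations are centred on the
    log median; the pooled standard deviation of those residuals is the
    stage's sigma.
    """
    out = {}
    for stage, so in stage_obs.items():
        resid = []
        for _, grp in so.records[so.records["survived"]].groupby("temperature_c"):
            t = grp["time_days"].to_numpy(dtype=float)
            if len(t) >= 2:
                resid.append(np.log(t) - np.log(np.median(t)))
        out[stage] = float(np.std(np.concatenate(resid))) if resid else 0.1
    return out


def fit_all(table: pd.DataFrame, cfg: RunConfig) -> dict:
    """Fit every temperature-driven process and return the component dict."""
    fc = cfg.fitting
    stage_obs = {s: obs_io.stage_observations_from_table(table, s)
                 for s in ("egg", "nymph", "pre_adult")}
    components: dict = {}
    linear_fits: dict = {}

    for stage, so in stage_obs.items():
        rates = rates_from_times(so)
        window = fc.linear_windows.get(stage, (15.0, 35.0))
        try:
            linear_fits[stage] = fit_linear_dd(rates, window)
            thr = linear_fits[stage].thresholds
            logger.info("linear %s: Tmin=%.2f C, K=%.1f DD",
                        stage, thr.Tmin, thr.K)
        except FitError as exc:
            logger.warning("linear fit skipped for %s: %s", stage, exc)
        candidates = []
        for family in fc.development_candidates.get(stage, []):
            try:
                candidates.append(fit_nonlinear(
                    rates.temperatures, rates.rates, family,
                    n_starts=fc.n_starts, seed=fc.fit_seed))
            except FitError as exc:
                logger.warning("%s fit failed for %s: %s", family, stage, exc)
        best = select_model(candidates)
        logger.info("development %s: %s AIC=%.2f R2=%.3f params=%s",
                    stage, best.family, best.aic, best.r2, best.params)
        components[f"development_{stage}"] = best

        mort = mortality_from_observations(so)
        mort_candidates = []
        for family in fc.mortality_candidates.get(stage, []):
            try:
                mort_candidates.append(fit_nonlinear(
                    mort["temperature_c"].to_numpy(),
                    mort["mortality"].to_numpy(), family,
                    n_starts=fc.n_starts, seed=fc.fit_seed))
            except FitError as exc:
                logger.warning("%s fit failed for %s mortality: %s",
                               family, stage, exc)
        components[f"mortality_{stage}"] = select_model(mort_candidates)

    # reproduction: lifetime totals per female -> Wang 7 over temperature
    diaries = obs_io.fecundity_diaries(table)
    if diaries.empty:
        raise FitError("no oviposition records in input")
    totals = diaries.groupby(["temperature_c", "individual_id"])["count"].sum()
    mean_total = totals.groupby("temperature_c").mean()
    components["fecundity"] = fit_nonlinear(
        mean_total.index.to_numpy(dtype=float), mean_total.to_numpy(dtype=float),
        "wang7", n_starts=fc.n_starts, seed=fc.fit_seed)

    # adult longevity -> senescence rates (reciprocal mean lifespans)
    longevity = obs_io.longevity_records(table)
    if longevity.empty:
        raise FitError("no adult longevity records in input")
    sen = {}
    for sex, family in (("female", "hilbert_logan3"), ("male", "exp_simple")):
        mean_life = longevity[longevity["sex"] == sex].groupby(
            "temperature_c")["lifespan_days"].mean()
        sen[sex] = fit_nonlinear(
            mean_life.index.to_numpy(dtype=float),
            1.0 / mean_life.to_numpy(dtype=float),
            family, n_starts=fc.n_starts, seed=fc.fit_seed)
    components["senescence_female"] = sen["female"]
    components["senescence_male"] = sen["male"]

    # age-structured oviposition: pooled cumulative fractions over
    # normalised age (per-temperature mean female lifespan as denominator)
    female_life = longevity[longevity["sex"] == "female"].groupby(
        "temperature_c")["lifespan_days"].mean()
    E, frac = [], []
    for (T, ind), grp in diaries.groupby(["temperature_c", "individual_id"]):
        total = grp["count"].sum()
        L = female_life.get(T, np.nan)
        if total <= 0 or not np.isfinite(L) or L <= 0:
            continue
        grp = grp.sort_values("day")
        E.extend(grp["day"].to_numpy(dtype=float) / L)
        frac.extend(np.cumsum(grp["count"].to_numpy(dtype=float)) / total)
    if not E:
        raise FitError("no usable oviposition diaries for the age CDF")
    components["oviposition"] = fit_nonlinear(
        np.asarray(E), np.asarray(frac), "oviposition_cdf",
        n_starts=fc.n_starts, seed=fc.fit_seed)

    components["_sigmas"] = estimate_sigmas(stage_obs)
    components["_linear"] = linear_fits
    return components


def run_pipeline(cfg: RunConfig) -> Path:
    """Execute fit → assemble → life table → (optional) map; return out dir."""
    out = Path(cfg.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    handler = logging.FileHandler(out / "run.log")
    handler.setFormatter(logging.Formatter("%(asctime)s %(levelname)s %(message)s"))
    logger.addHandler(handler)
    logger.setLevel(logging.INFO)
    try:
        return _run(cfg, out)
    finally:
        logger.removeHandler(handler)
        handler.close()


def _run(cfg: RunConfig, out: Path) -> Path:
    stage = "read"
    try:
        table = obs_io.read_observation_table(cfg.observations)
        stage = "fit"
        components = fit_all(table, cfg)
        sigmas = components.pop("_sigmas")
        linear_fits = components.pop("_linear")

        stage = "assemble"
        model = build_phenology(components, female_ratio=cfg.female_ratio,
                                sigmas=sigmas)
        bundle = {k: getattr(v, "params", v) for k, v in components.items()}
        for s, fit in linear_fits.items():
            bundle[f"linear_{s}"] = fit.params
        tm.save_param_bundle(bundle, out / "fitted_params.json")

        stage = "life_table"
        sim = cfg.simulation
        report = replicate_simulation(
            model, sim.temperatures, n_eggs=sim.n_eggs, n_reps=sim.n_reps,
            base_seed=sim.seed, horizon=sim.horizon)
        report.to_csv(out / "life_table.csv", index=False)
        logger.info("life-table report written (%d rows)", len(report))

        raster_paths: dict = {}
        if cfg.mapping is not None:
            stage = "map"
            grid = grid_from_directory(cfg.mapping.grid_dir)
            for delta in cfg.mapping.delta_t:
                scen = apply_scenario_offset(grid, delta) if delta else grid
                indices = map_indices(model, scen)
                sub = out / f"indices_delta_{delta:+.1f}".replace("+", "p").replace(
                    "-", "m").replace(".", "_")
                raster_paths[str(delta)] = write_index_rasters(indices, sub)
    except Exception as exc:
        logger.error("pipeline failed at stage %r: %s", stage, exc)
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc

    manifest = {
        "package_version": __version__,
        "config": json.loads(cfg.model_dump_json()),
        "input_sha256": {str(cfg.observations): _sha256(cfg.observations)},
        "seeds": {"fit": cfg.fitting.fit_seed, "simulation": cfg.simulation.seed},
        "outputs": {
            "fitted_params": "fitted_params.json",
            "life_table": "life_table.csv",
            "rasters": raster_paths,
        },
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                  sort_keys=True) + "\n")
    return out
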