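"""Synthetic individual-level experiments from a known phenology model.

The generator emulates a constant-temperature laboratory design for a
cricket-like insect: cohorts of eggs followed individually through the
egg, nymph and pre-adult stages at nine constant temperatures between 10
and 40 °C (100 eggs per temperature), oviposition diaries of 20 adult
pairs per temperature, and adult longevity cohorts of 50 individuals per
sex per temperature.  All observations are drawn from known "true"
thermal-response curves plus individual variability, so the full fitting
pipeline can be exercised and checked for parameter recovery without any
external data.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import thermal_models as tm
from .life_table import PhenologyModel
from .spatial import ClimateGrid, GridGeometry

__all__ = [
    "TrueModelSpec",
    "SyntheticExperiment",
    "DESIGN_TEMPERATURES",
    "generate_development_data",
    "generate_fecundity_data",
    "generate_longevity_data",
    "generate_experiment",
    "generate_climate_grid",
]

#: the constant-temperature design: nine regimes spanning 10–40 °C
DESIGN_TEMPERATURES = (10.0, 15.0, 20.0, 23.0, 25.0, 30.0, 35.0, 37.0, 40.0)

OBS_COLUMNS = ["stage", "temperature_c", "individual_id", "event", "day", "count"]


@dataclass(frozen=True)
class TrueModelSpec:
    """A phenology model designated as ground truth, plus observation noise.

    ``egg_dispersion`` is the negative-binomial size parameter of daily
    egg counts (smaller = more overdispersed); development-time spread
    comes from each stage's lognormal sigma inside the model.
    """

    model: PhenologyModel
    egg_dispersion: float = 5.0

    def __post_init__(self):
        if self.egg_dispersion <= 0:
            raise ValueError("egg_dispersion must be > 0")


@dataclass
class SyntheticExperiment:
    """One generated experiment: observations, diaries, longevities, provenance."""

    development: pd.DataFrame
    fecundity: pd.DataFrame
    longevity: pd.DataFrame
    provenance: dict

    def write(self, directory) -> dict:
        """Write the CSVs plus a provenance manifest; returns name->path."""
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        paths = {}
        for name, frame in (("development", self.development),
                            ("fecundity", self.fecundity),
                            ("longevity", self.longevity)):
            p = directory / f"{name}.csv"
            frame.to_csv(p, index=False)
            paths[name] = str(p)
        manifest = directory / "truth.json"
        manifest.write_text(json.dumps(self.provenance, indent=2, sort_keys=True)
                            + "\n")
        paths["truth"] = str(manifest)
        return paths

    def digest(self) -> str:
        """SHA-256 over the CSV-rendered content; identical seeds ⇒ identical digest."""
        h = hashlib.sha256()
        for frame in (self.development, self.fecundity, self.longevity):
            h.update(frame.to_csv(index=False).encode())
        return h.hexdigest()


def generate_development_data(
    spec: TrueModelSpec,
    temperatures: Sequence[float] = DESIGN_TEMPERATURES,
    n_per_temp: int = 100,
    seed: int = 0,
) -> pd.DataFrame:
    """Individual stage-transition records in the observation CSV schema.

    Each egg is followed through the stages.  Per stage: survival is
    Bernoulli(1 − m(T)); completers get a lognormal duration with median
    1/r(T) (recorded as a ``molt`` row whose ``day`` is the duration);
    non-survivors are censored at a uniform fraction of their would-be
    duration (a ``death`` row).  Temperatures where a stage's development
    rate is non-positive yield all-death records for that stage.
    """
    if n_per_temp < 1:
        raise ValueError("n_per_temp must be >= 1")
    rng = np.random.default_rng(seed)
    model = spec.model
    rows = []
    for T in temperatures:
        alive = np.arange(n_per_temp)
        for st in model.stages:
            if len(alive) == 0:
                break
            r = tm.development_rate(st.development, T)
            m = tm.eval_wang_mortality(st.mortality, T)
            n = len(alive)
            if r <= 0:
                # no development possible: the whole stage cohort dies
                day = np.maximum(1, np.ceil(rng.exponential(30.0, n)))
                for ind, d in zip(alive, day):
                    rows.append((st.name, T, int(ind), "death", float(d), ""))
                alive = alive[:0]
                continue
            dur = np.maximum(1.0, np.round(
                (1.0 / r) * np.exp(st.sigma * rng.standard_normal(n))))
            dies = rng.random(n) < m
            censor = np.maximum(1.0, np.ceil(rng.random(n) * dur))
            for ind, d, dead, c in zip(alive, dur, dies, censor):
                if dead:
                    rows.append((st.name, T, int(ind), "death", float(c), ""))
                else:
                    rows.append((st.name, T, int(ind), "molt", float(d), ""))
            alive = alive[~dies]
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


def generate_fecundity_data(
    spec: TrueModelSpec,
    temperatures: Sequence[float] = DESIGN_TEMPERATURES,
    n_pairs: int = 20,
    seed: int = 0,
) -> pd.DataFrame:
    """Daily egg-count diaries per female (observation schema, oviposition rows).

    Each female draws an exponential lifespan at the female senescence
    rate; her expected eggs on adult day t are f(T)·ΔO(t/L) with L the
    mean lifespan, and the recorded count is negative-binomially
    overdispersed around that mean.  Zero-count days are recorded too, so
    the adult pre-oviposition period emerges as the first nonzero day.
    """
    if n_pairs < 1:
        raise ValueError("n_pairs must be >= 1")
    rng = np.random.default_rng(seed)
    model = spec.model
    k = spec.egg_dispersion
    rows = []
    for T in temperatures:
        f = tm.eval_wang7_fecundity(model.fecundity, T)
        s = tm.eval_senescence(model.senescence_female, T)
        L = 1.0 / s if s > 0 else 365.0
        for ind in range(n_pairs):
            span = max(1, int(round(rng.exponential(L))) if s > 0 else int(L))
            t = np.arange(span + 1)
            cdf = tm.eval_oviposition_cdf(model.oviposition, t / L)
            mu = f * np.diff(cdf)
            counts = np.where(
                mu > 0, rng.negative_binomial(k, k / (k + np.maximum(mu, 1e-12))), 0)
            for day, cnt in enumerate(counts, start=1):
                rows.append(("adult_female", T, ind, "oviposition",
                             float(day), int(cnt)))
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


def generate_longevity_data(
    spec: TrueModelSpec,
    temperatures: Sequence[float] = DESIGN_TEMPERATURES,
    n_per_sex: int = 50,
    seed: int = 0,
) -> pd.DataFrame:
    """Adult longevity records per sex: exponential lifespans at s(T)."""
    if n_per_sex < 1:
        raise ValueError("n_per_sex must be >= 1")
    rng = np.random.default_rng(seed)
    model = spec.model
    rows = []
    for T in temperatures:
        for sex, curve in (("female", model.senescence_female),
                           ("male", model.senescence_male)):
            s = tm.eval_senescence(curve, T)
            if s > 0:
                span = np.maximum(1.0, np.round(rng.exponential(1.0 / s, n_per_sex)))
            else:
                span = np.full(n_per_sex, 365.0)
            for ind, d in enumerate(span):
                rows.append((f"adult_{sex}", T, ind, "death", float(d), ""))
    return pd.DataFrame(rows, columns=OBS_COLUMNS)


def generate_experiment(
    spec: TrueModelSpec,
    temperatures: Sequence[float] = DESIGN_TEMPERATURES,
    n_per_temp: int = 100,
    n_pairs: int = 20,
    n_per_sex: int = 50,
    seed: int = 0,
) -> SyntheticExperiment:
    """The full design at one seed; sub-seeds are spawned deterministically."""
    ss = np.random.SeedSequence(seed)
    s_dev, s_fec, s_lon = [int(c.generate_state(1)[0] % (2**31))
                           for c in ss.spawn(3)]
    dev = generate_development_data(spec, temperatures, n_per_temp, s_dev)
    fec = generate_fecundity_data(spec, temperatures, n_pairs, s_fec)
    lon = generate_longevity_data(spec, temperatures, n_per_sex, s_lon)
    provenance = {
        "seed": seed,
        "design": {
            "temperatures": list(map(float, temperatures)),
            "n_eggs_per_temperature": n_per_temp,
            "n_oviposition_pairs": n_pairs,
            "n_adults_per_sex": n_per_sex,
        },
        "true_parameters": _model_provenance(spec.model),
        "egg_dispersion": spec.egg_dispersion,
    }
    return SyntheticExperiment(development=dev, fecundity=fec, longevity=lon,
                               provenance=provenance)


def _model_provenance(model: PhenologyModel) -> dict:
    out = {"female_ratio": model.female_ratio, "stages": {}}
    for st in model.stages:
        out["stages"][st.name] = {
            "development": tm.params_to_dict(st.development),
            "mortality": tm.params_to_dict(st.mortality),
            "sigma": st.sigma,
        }
    out["fecundity"] = tm.params_to_dict(model.fecundity)
    out["oviposition"] = tm.params_to_dict(model.oviposition)
    out["senescence_female"] = tm.params_to_dict(model.senescence_female)
    out["senescence_male"] = tm.params_to_dict(model.senescence_male)
    return out


def generate_climate_grid(
    shape: tuple[int, int],
    pattern: str = "constant",
    params: Optional[dict] = None,
    seed: int = 0,
    nodata_border: int = 0,
    seasonal_amplitude: float = 0.0,
) -> ClimateGrid:
    """Synthetic georeferenced monthly-mean grid for exercising the mapper.

    Patterns: ``constant`` (params: value), ``gradient`` (north–south,
    params: low/high), ``checkerboard`` (params: low/high).  A seasonal
    sine of the given amplitude modulates the twelve monthly layers, and
    ``nodata_border`` masks that many edge cells.
    """
    nrows, ncols = shape
    if nrows < 1 or ncols < 1:
        raise ValueError("shape must be positive")
    params = params or {}
    if pattern == "constant":
        base = np.full(shape, float(params.get("value", 30.0)))
    elif pattern == "gradient":
        low = float(params.get("low", 15.0))
        high = float(params.get("high", 35.0))
        base = np.repeat(np.linspace(high, low, nrows)[:, None], ncols, axis=1)
    elif pattern == "checkerboard":
        low = float(params.get("low", 10.0))
        high = float(params.get("high", 30.0))
        ij = np.add.outer(np.arange(nrows), np.arange(ncols))
        base = np.where(ij % 2 == 0, high, low)
    else:
        raise ValueError(f"unknown pattern {pattern!r}")
    season = seasonal_amplitude * np.sin(2 * np.pi * np.arange(12) / 12.0)
    tmean = base[None, :, :] + season[:, None, None]
    mask = np.ones(shape, dtype=bool)
    if nodata_border > 0:
        b = nodata_border
        inner = np.zeros(shape, dtype=bool)
        inner[b:nrows - b, b:ncols - b] = True
        mask &= inner
    geom = GridGeometry(ncols=ncols, nrows=nrows, xllcorner=30.0,
                        yllcorner=-5.0, cellsize=0.5)
    return ClimateGrid(tmean=tmean, geometry=geom, mask=mask)
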