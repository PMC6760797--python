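"""Climate-grid risk indices from a phenology model.

Monthly temperature grids are evaluated cell by cell with the
deterministic life-table machinery to produce three continuous indices:

* ERI — establishment risk index, the mean over the twelve months of the
  product over immature stages of (1 − stage mortality); 1 where every
  stage survives all year, 0 where any stage is certainly killed.
* GI — generations per year, the sum over the 365 interpolated days of
  the reciprocal generation length at that day's temperature (immature
  development plus adult maturation to the 50% oviposition age).
* AI — activity index, log10 of the yearly finite population growth,
  Σ rm(T_month)·days_month / ln 10; months where the population is not
  viable contribute a decline at the adult female senescence rate.

Grids are 12 monthly layers of mean (optionally min/max) temperature on
one shared geometry; I/O uses the plain-text ESRI ASCII raster format.
A future-warming scenario is a uniform ΔT offset of every defined cell.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Optional

import numpy as np

from . import thermal_models as tm
from .life_table import PhenologyModel, deterministic_schedule, life_table_params

__all__ = [
    "GridGeometry",
    "ClimateGrid",
    "RiskIndexGrid",
    "read_ascii_grid",
    "write_ascii_grid",
    "monthly_to_daily",
    "cell_indices",
    "map_indices",
    "apply_scenario_offset",
]

MONTH_LENGTHS = np.array([31, 28, 31, 30, 31, 30, 31, 31, 30, 31, 30, 31])
MONTH_STARTS = np.concatenate([[0], np.cumsum(MONTH_LENGTHS)[:-1]])
MONTH_MIDPOINTS = MONTH_STARTS + MONTH_LENGTHS / 2.0


@dataclass(frozen=True)
class GridGeometry:
    """Raster geometry of an ESRI ASCII grid (lower-left corner origin)."""

    ncols: int
    nrows: int
    xllcorner: float
    yllcorner: float
    cellsize: float
    nodata: float = -9999.0


@dataclass
class ClimateGrid:
    """Twelve monthly temperature layers on one shared raster geometry.

    ``tmean`` has shape (12, nrows, ncols); ``tmin``/``tmax`` are optional
    companions carried for extension (the indices use the mean only).
    ``mask`` is True on valid cells.
    """

    tmean: np.ndarray
    geometry: GridGeometry
    mask: np.ndarray = None
    tmin: Optional[np.ndarray] = None
    tmax: Optional[np.ndarray] = None

    def __post_init__(self):
        self.tmean = np.asarray(self.tmean, dtype=float)
        if self.tmean.shape[0] != 12:
            raise ValueError("tmean must have 12 monthly layers")
        shape = self.tmean.shape[1:]
        if shape != (self.geometry.nrows, self.geometry.ncols):
            raise ValueError("layer shape does not match geometry")
        if self.mask is None:
            self.mask = np.ones(shape, dtype=bool)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != shape:
            raise ValueError("mask misaligned with layers")
        for name in ("tmin", "tmax"):
            layer = getattr(self, name)
            if layer is not None and np.asarray(layer).shape != self.tmean.shape:
                raise ValueError(f"{name} misaligned with tmean")
        if self.tmin is not None and self.tmax is not None:
            valid = self.mask[None, :, :] & np.ones((12, 1, 1), dtype=bool)
            if np.any(self.tmin[valid] > self.tmean[valid] + 1e-9) or np.any(
                self.tmean[valid] > self.tmax[valid] + 1e-9
            ):
                raise ValueError("requires tmin <= tmean <= tmax on valid cells")


@dataclass
class RiskIndexGrid:
    """Per-cell establishment (ERI), generation (GI) and activity (AI) indices."""

    eri: np.ndarray
    gi: np.ndarray
    ai: np.ndarray
    geometry: GridGeometry
    mask: np.ndarray


def read_ascii_grid(path) -> tuple[np.ndarray, GridGeometry]:
    """Read one ESRI ASCII raster; nodata cells come back as NaN."""
    lines = Path(path).read_text().splitlines()
    header: dict[str, float] = {}
    i = 0
    while i < len(lines) and lines[i].split() and not _is_number(lines[i].split()[0]):
        key, value = lines[i].split(maxsplit=1)
        header[key.lower()] = float(value)
        i += 1
    required = {"ncols", "nrows", "xllcorner", "yllcorner", "cellsize"}
    if not required <= set(header):
        raise ValueError(f"{path}: missing header fields {sorted(required - set(header))}")
    nodata = header.get("nodata_value", -9999.0)
    geom = GridGeometry(
        ncols=int(header["ncols"]), nrows=int(header["nrows"]),
        xllcorner=header["xllcorner"], yllcorner=header["yllcorner"],
        cellsize=header["cellsize"], nodata=nodata,
    )
    data = np.loadtxt(lines[i:], dtype=float).reshape(geom.nrows, geom.ncols)
    data[data == nodata] = np.nan
    return data, geom


def write_ascii_grid(path, data: np.ndarray, geom: GridGeometry) -> None:
    """Write one layer as ESRI ASCII, mapping NaN to the nodata value."""
    out = np.where(np.isnan(data), geom.nodata, data)
    with open(path, "w") as fh:
        fh.write(f"ncols {geom.ncols}\n"
                 f"nrows {geom.nrows}\n"
                 f"xllcorner {geom.xllcorner!r}\n"
                 f"yllcorner {geom.yllcorner!r}\n"
                 f"cellsize {geom.cellsize!r}\n"
                 f"NODATA_value {geom.nodata!r}\n")
        for row in out:
            fh.write(" ".join(repr(float(v)) for v in row) + "\n")


def _is_number(tok: str) -> bool:
    try:
        float(tok)
        return True
    except ValueError:
        return False


def grid_from_directory(directory) -> ClimateGrid:
    """Load tmean_01.asc … tmean_12.asc (plus optional tmin_/tmax_) layers."""
    directory = Path(directory)

    def load(prefix):
        layers, geom0 = [], None
        for month in range(1, 13):
            p = directory / f"{prefix}_{month:02d}.asc"
            if not p.exists():
                return None, None
            data, geom = read_ascii_grid(p)
            if geom0 is None:
                geom0 = geom
            elif geom != geom0:
                raise ValueError(f"{p}: geometry differs across layers")
            layers.append(data)
        return np.stack(layers), geom0

    tmean, geom = load("tmean")
    if tmean is None:
        raise FileNotFoundError(f"no tmean_01.asc … tmean_12.asc in {directory}")
    tmin, gmin = load("tmin")
    tmax, gmax = load("tmax")
    for g in (gmin, gmax):
        if g is not None and g != geom:
            raise ValueError("tmin/tmax geometry differs from tmean")
    mask = ~np.any(np.isnan(tmean), axis=0)
    return ClimateGrid(tmean=tmean, geometry=geom, mask=mask, tmin=tmin, tmax=tmax)


def grid_to_directory(grid: ClimateGrid, directory) -> None:
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    for name in ("tmean", "tmin", "tmax"):
        layers = getattr(grid, name)
        if layers is None:
            continue
        for month in range(12):
            data = np.where(grid.mask, layers[month], np.nan)
            write_ascii_grid(directory / f"{name}_{month + 1:02d}.asc",
                             data, grid.geometry)


def monthly_to_daily(monthly) -> np.ndarray:
    """Periodic linear interpolation of 12 monthly values to 365 daily ones.

    Values sit at month midpoints of a 365-day year and wrap around the
    new year, so the daily series is continuous and bounded by the
    monthly extremes; its mean tracks the monthly mean closely.
    """
    monthly = np.asarray(monthly, dtype=float)
    if monthly.shape != (12,):
        raise ValueError("need exactly 12 monthly values")
    if np.any(np.isnan(monthly)):
        return np.full(365, np.nan)
    xp = np.concatenate([[MONTH_MIDPOINTS[-1] - 365.0], MONTH_MIDPOINTS,
                         [MONTH_MIDPOINTS[0] + 365.0]])
    fp = np.concatenate([[monthly[-1]], monthly, [monthly[0]]])
    return np.interp(np.arange(365) + 0.5, xp, fp)


class _CellEngine:
    """Caches per-temperature life-table quantities (keyed at 0.01 °C)."""

    def __init__(self, model: PhenologyModel, horizon: int = 1500):
        self.model = model
        self.horizon = horizon
        self._cache: dict[int, tuple[float, float, float]] = {}
        # 50% oviposition point on the normalised age axis
        from scipy.optimize import brentq
        o = lambda e: tm.eval_oviposition_cdf(model.oviposition, e) - 0.5
        if o(10.0) < 0:
            self.e50 = 10.0
        else:
            self.e50 = float(brentq(o, 0.0, 10.0, xtol=1e-8))

    def at(self, T: float) -> tuple[float, float, float]:
        """(stage-survival product, 1/generation-length, rm-or-decline) at T."""
        key = int(round(T * 100))
        hit = self._cache.get(key)
        if hit is not None:
            return hit
        T = key / 100.0
        surv = self.model.immature_survival(T)
        durations = self.model.stage_durations(T)
        s_f = tm.eval_senescence(self.model.senescence_female, T)
        if durations is None or sum(durations) > self.horizon:
            inv_gen = 0.0
            rm = -s_f if s_f > 0 else 0.0
            rm = -abs(rm)
        else:
            maturation = self.e50 * (1.0 / s_f if s_f > 0
                                     else self.horizon - sum(durations))
            inv_gen = 1.0 / (sum(durations) + maturation)
            sched = deterministic_schedule(self.model, T, horizon=self.horizon)
            params = life_table_params(sched)
            if np.isfinite(params.rm):
                rm = params.rm
            else:
                rm = -s_f if s_f > 0 else 0.0
                rm = -abs(rm)
        out = (surv, inv_gen, rm)
        self._cache[key] = out
        return out


def cell_indices(model: PhenologyModel, daily: np.ndarray,
                 engine: Optional[_CellEngine] = None):
    """(ERI, GI, AI) for one cell's 365-day temperature series."""
    daily = np.asarray(daily, dtype=float)
    if daily.shape != (365,):
        raise ValueError("daily series must have length 365")
    if np.any(np.isnan(daily)):
        return (np.nan, np.nan, np.nan)
    engine = engine or _CellEngine(model)
    monthly = np.array([
        daily[s:s + n].mean() for s, n in zip(MONTH_STARTS, MONTH_LENGTHS)
    ])
    eri = 0.0
    ai = 0.0
    for Tm, ndays in zip(monthly, MONTH_LENGTHS):
        surv, _, rm = engine.at(Tm)
        eri += surv / 12.0
        ai += rm * ndays
    gi = float(sum(engine.at(Td)[1] for Td in daily))
    return float(eri), gi, float(ai / math.log(10.0))


def map_indices(model: PhenologyModel, grid: ClimateGrid) -> RiskIndexGrid:
    """Apply cell_indices to every valid cell; nodata propagates."""
    engine = _CellEngine(model)
    shape = grid.tmean.shape[1:]
    eri = np.full(shape, np.nan)
    gi = np.full(shape, np.nan)
    ai = np.full(shape, np.nan)
    for i in range(shape[0]):
        for j in range(shape[1]):
            if not grid.mask[i, j]:
                continue
            daily = monthly_to_daily(grid.tmean[:, i, j])
            eri[i, j], gi[i, j], ai[i, j] = cell_indices(model, daily, engine)
    return RiskIndexGrid(eri=eri, gi=gi, ai=ai,
                         geometry=grid.geometry, mask=grid.mask.copy())


def apply_scenario_offset(grid: ClimateGrid, delta: float) -> ClimateGrid:
    """Uniform warming scenario: shift every defined cell by delta °C."""
    if not np.isfinite(delta):
        raise ValueError("delta must be finite")
    shift = lambda a: None if a is None else a + delta
    return ClimateGrid(
        tmean=grid.tmean + delta,
        geometry=grid.geometry,
        mask=grid.mask.copy(),
        tmin=shift(grid.tmin),
        tmax=shift(grid.tmax),
    )


def write_index_rasters(indices: RiskIndexGrid, directory) -> dict:
    """Write eri/gi/ai as single-band ASCII rasters; returns name->path."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    out = {}
    for name in ("eri", "gi", "ai"):
        data = np.where(indices.mask, getattr(indices, name), np.nan)
        path = directory / f"{name}.asc"
        write_ascii_grid(path, data, indices.geometry)
        out[name] = str(path)
    return out
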