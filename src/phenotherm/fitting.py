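"""Fitting thermal-response curves to observed life-history data.

The fitting substrate is per-individual records of stage development
(duration in days for completers, censoring time for deaths).  Rates are
the reciprocal of the median development time at each temperature; stage
mortality is the fraction of entrants failing the stage.  The linear
degree-day model is fit by ordinary least squares on a stated sub-optimal
temperature window; the nonlinear families are fit by Marquardt-style
damped least squares (trust-region reflective, honouring parameter
bounds) from Latin-hypercube multi-starts, and candidates are
compared by AIC (n·ln(RSS/n) + 2k) with R² as tie-break.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy.optimize import least_squares
from scipy.stats import qmc

from . import thermal_models as tm

__all__ = [
    "StageObservations",
    "RateTable",
    "FitResult",
    "FitError",
    "rates_from_times",
    "mortality_from_observations",
    "fit_linear_dd",
    "fit_nonlinear",
    "select_model",
    "FAMILY_BOUNDS",
]


class FitError(RuntimeError):
    """Raised when no usable fit can be produced."""


@dataclass
class StageObservations:
    """Per-individual development records for one life stage.

    ``records`` columns: temperature_c, individual_id, time_days
    (stage duration for completers, censoring time otherwise), survived
    (True when the individual completed the stage).
    """

    stage: str
    records: pd.DataFrame

    def __post_init__(self):
        required = {"temperature_c", "individual_id", "time_days", "survived"}
        missing = required - set(self.records.columns)
        if missing:
            raise ValueError(f"missing record columns: {sorted(missing)}")
        if len(self.records) and (self.records["time_days"] <= 0).any():
            raise ValueError("non-positive development/censoring times")
        dup = self.records.duplicated(["temperature_c", "individual_id"])
        if dup.any():
            raise ValueError("duplicate (temperature, individual) records")


@dataclass
class RateTable:
    """Per-temperature median development times and their reciprocal rates."""

    stage: str
    table: pd.DataFrame  # temperature_c, median_days, rate, n
    excluded: list = field(default_factory=list)  # temps with zero completers

    @property
    def temperatures(self) -> np.ndarray:
        return self.table["temperature_c"].to_numpy()

    @property
    def rates(self) -> np.ndarray:
        return self.table["rate"].to_numpy()


@dataclass
class FitResult:
    """A fitted curve plus its goodness-of-fit bookkeeping."""

    family: str
    params: object
    se: dict
    rss: float
    r2: float
    aic: float
    n: int
    k: int
    converged: bool
    message: str = ""
    condition_number: Optional[float] = None
    underdetermined: bool = False
    thresholds: Optional[tm.ThermalThresholds] = None


def aic_least_squares(rss: float, n: int, k: int) -> float:
    """AIC for Gaussian least squares with constants dropped: n·ln(RSS/n) + 2k."""
    return n * np.log(max(rss, 1e-300) / n) + 2 * k


def rates_from_times(obs: StageObservations) -> RateTable:
    """Median development time and reciprocal rate per temperature.

    Only completers contribute; temperatures with no completer are listed
    in ``excluded`` rather than given a row.  The median of an even-sized
    sample is the midpoint of the two central values.
    """
    if obs.records.empty:
        raise FitError(f"no observations for stage {obs.stage!r}")
    rows, excluded = [], []
    for T, grp in obs.records.groupby("temperature_c"):
        done = grp.loc[grp["survived"], "time_days"]
        if len(done) == 0:
            excluded.append(float(T))
            continue
        med = float(done.median())
        rows.append((float(T), med, 1.0 / med, int(len(done))))
    if not rows:
        raise FitError(f"no temperature with completers for stage {obs.stage!r}")
    table = pd.DataFrame(rows, columns=["temperature_c", "median_days", "rate", "n"])
    return RateTable(stage=obs.stage, table=table, excluded=excluded)


def mortality_from_observations(obs: StageObservations) -> pd.DataFrame:
    """Per-temperature fraction of entrants failing the stage, with binomial n."""
    rows = []
    for T, grp in obs.records.groupby("temperature_c"):
        n = len(grp)
        died = int((~grp["survived"]).sum())
        rows.append((float(T), died / n, n))
    return pd.DataFrame(rows, columns=["temperature_c", "mortality", "n"])


def fit_linear_dd(rates: RateTable, temp_window: Sequence[float]) -> FitResult:
    """OLS fit of the linear degree-day model on a sub-optimal window.

    The window excludes supra-optimal temperatures where the rate curve
    bends over; the result carries Tmin = −a/b and K = 1/b as thresholds.
    """
    lo, hi = temp_window
    mask = (rates.temperatures >= lo) & (rates.temperatures <= hi)
    T = rates.temperatures[mask]
    r = rates.rates[mask]
    if len(T) < 3:
        raise FitError(f"need >=3 temperatures in window [{lo}, {hi}], got {len(T)}")
    if np.ptp(T) == 0:
        raise FitError("singular design: all temperatures equal")
    X = sm.add_constant(T)
    res = sm.OLS(r, X).fit()
    a, b = float(res.params[0]), float(res.params[1])
    params = tm.LinearDDParams(a=a, b=b)
    rss = float(res.ssr)
    n = len(T)
    return FitResult(
        family="linear",
        params=params,
        se={"a": float(res.bse[0]), "b": float(res.bse[1])},
        rss=rss,
        r2=float(res.rsquared),
        aic=aic_least_squares(rss, n, 2),
        n=n,
        k=2,
        converged=True,
        condition_number=float(np.linalg.cond(X)),
        thresholds=tm.thresholds_from_model(params),
    )


# Per-family parameter boxes for Latin-hypercube initialisation and bounds.
# Data-dependent entries are callables of (x, y).
FAMILY_BOUNDS: dict[str, dict] = {
    "logan1": {
        "names": ("Y", "p", "Tmax", "v"),
        "bounds": lambda x, y: [
            (1e-5, max(y.max(), 1e-3)),
            (0.01, 0.5),
            (x.max() + 0.5, x.max() + 15.0),
            (0.5, 12.0),
        ],
        "build": lambda v: tm.Logan1Params(*v),
        "eval": lambda p, x: tm.eval_logan1(p, x, clip=False),
    },
    "allahyari": {
        "names": ("P", "Tmin", "Tmax", "n", "m"),
        "bounds": lambda x, y: [
            (1e-3, 50.0),
            (x.min() - 15.0, x.min() + 4.0),
            (x.max() + 0.5, x.max() + 15.0),
            (0.2, 8.0),
            (0.01, 5.0),
        ],
        "build": lambda v: tm.AllahyariParams(*v),
        "eval": lambda p, x: tm.eval_allahyari(p, x, clip=False),
    },
    "wang2": {
        "names": ("Tl", "Th", "B", "H"),
        "bounds": lambda x, y: [
            (x.min() - 10.0, x.min() + 8.0),
            (x.max() - 8.0, x.max() + 10.0),
            (0.1, 6.0),
            (1e-4, 0.5),
        ],
        "build": lambda v: tm.WangMortalityParams(
            variant="two_sided", Tl=v[0], Th=v[1], B=v[2], H=v[3]
        ),
        "eval": lambda p, x: tm.eval_wang_mortality(p, x),
    },
    "wang3": {
        "names": ("Topt", "B", "H"),
        "bounds": lambda x, y: [
            (x.min(), x.max()),
            (0.3, 8.0),
            (1e-4, 0.5),
        ],
        "build": lambda v: tm.WangMortalityParams(
            variant="symmetric", Topt=v[0], B=v[1], H=v[2]
        ),
        "eval": lambda p, x: tm.eval_wang_mortality(p, x),
    },
    "wang7": {
        "names": ("Fmax", "Topt", "B1", "Bh"),
        "bounds": lambda x, y: [
            (0.2 * y.max(), 3.0 * max(y.max(), 1.0)),
            (x.min(), x.max()),
            (0.3, 10.0),
            (0.3, 10.0),
        ],
        "build": lambda v: tm.Wang7Params(Fmax=v[0], Topt=v[1], B1=v[2], Bh=v[3]),
        "eval": lambda p, x: tm.eval_wang7_fecundity(p, x),
    },
    "oviposition_cdf": {
        "names": ("a", "b", "c"),
        "bounds": lambda x, y: [(0.0, 4.0), (0.0, 4.0), (0.0, 4.0)],
        "build": lambda v: tm.OvipositionCDFParams(*v),
        "eval": lambda p, x: tm.eval_oviposition_cdf(p, x),
    },
    "hilbert_logan3": {
        "names": ("trid", "Tmin", "Tmax", "D", "Dt"),
        "bounds": lambda x, y: [
            (1e-3, 2.0),
            (x.min() - 30.0, x.min() - 0.5),
            (x.max() + 1.0, x.max() + 40.0),
            (1.0, 1e4),
            (0.2, 25.0),
        ],
        "build": lambda v: tm.HilbertLogan3Params(*v),
        "eval": lambda p, x: tm.eval_senescence(p, x, clip=False),
    },
    "exp_simple": {
        "names": ("b1", "b2"),
        "bounds": lambda x, y: [(1e-8, max(y.max(), 1e-3)), (-0.5, 0.5)],
        "build": lambda v: tm.ExpSimpleParams(*v),
        "eval": lambda p, x: tm.eval_senescence(p, x, clip=False),
    },
}


def _lhs_starts(bounds, n_starts, seed):
    sampler = qmc.LatinHypercube(d=len(bounds), seed=seed)
    u = sampler.random(n=n_starts)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])
    return lo + u * (hi - lo)


def fit_nonlinear(
    x,
    y,
    family: str,
    n_starts: int = 25,
    seed: int = 0,
    extra_starts: Optional[Sequence[Sequence[float]]] = None,
) -> FitResult:
    """Damped least squares with Latin-hypercube multi-starts.

    The response surfaces of the Logan/Allahyari/Wang families are
    multimodal, so each fit is attempted from ``n_starts`` Latin-hypercube
    points inside the family's parameter box (plus any caller-supplied
    ``extra_starts``) and the converged fit with the lowest RSS wins.
    Standard errors come from the Jacobian-based covariance when available.
    """
    if family not in FAMILY_BOUNDS:
        raise ValueError(f"unknown model family {family!r}")
    spec = FAMILY_BOUNDS[family]
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ValueError("x and y must be matching 1-D arrays")
    names = spec["names"]
    bounds = spec["bounds"](x, y)
    k = len(names)
    underdetermined = len(x) < k

    starts = _lhs_starts(bounds, n_starts, seed)
    if extra_starts is not None:
        starts = np.vstack([np.asarray(extra_starts, dtype=float), starts])
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    def residual(values):
        try:
            model = spec["build"](values)
        except ValueError:
            return np.full_like(y, 1e6)
        r = spec["eval"](model, x) - y
        return np.where(np.isfinite(r), r, 1e6)

    # stop early once the surface is clearly solved or the multi-start
    # has plateaued; both rules are deterministic given the start list
    target_rss = 1e-14 * (float(np.sum(y**2)) + 1.0)
    best = None
    stale = 0
    for start in starts:
        try:
            res = least_squares(residual, np.clip(start, lo, hi),
                                bounds=(lo, hi), method="trf",
                                xtol=1e-8, ftol=1e-8, gtol=1e-8,
                                max_nfev=1000)
        except Exception:
            continue
        rss = float(np.sum(res.fun**2))
        # status 0 (iteration cap) still carries a usable minimum; only
        # genuinely failed evaluations are dropped
        if res.status < 0 or not np.isfinite(rss):
            continue
        if best is None or rss < best[0] * (1.0 - 1e-3):
            best = (rss, res)
            stale = 0
        else:
            stale += 1
        if best[0] < target_rss or stale >= 8:
            break

    if best is None:
        raise FitError(f"no start converged for family {family!r} "
                       f"({n_starts} Latin-hypercube starts)")
    # final polish at tight tolerance: the scan locates the basin, this
    # resolves weakly identified parameter combinations within it
    try:
        polished = least_squares(residual, best[1].x, bounds=(lo, hi),
                                 method="trf", xtol=1e-13, ftol=1e-13,
                                 gtol=1e-13, max_nfev=3000)
        prss = float(np.sum(polished.fun**2))
        if polished.status >= 0 and np.isfinite(prss) and prss <= best[0]:
            best = (prss, polished)
    except Exception:
        pass
    rss, res = best
    params = spec["build"](list(res.x))
    n = len(x)
    dof = n - k
    cond = None
    se_vals = np.full(k, np.nan)
    if dof > 0:
        jtj = res.jac.T @ res.jac
        cond = float(np.linalg.cond(jtj))
        cov = np.linalg.pinv(jtj) * rss / dof
        with np.errstate(invalid="ignore"):
            se_vals = np.sqrt(np.diag(cov))
    se = {nm: float(v) for nm, v in zip(names, se_vals)}
    tss = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else float("nan")
    thresholds = None
    if family in ("logan1", "allahyari"):
        try:
            thresholds = tm.thresholds_from_model(params)
        except tm.ThresholdUndefinedError:
            thresholds = None
    return FitResult(
        family=family,
        params=params,
        se=se,
        rss=rss,
        r2=r2,
        aic=aic_least_squares(rss, n, k),
        n=n,
        k=k,
        converged=True,
        condition_number=cond,
        underdetermined=underdetermined,
        thresholds=thresholds,
    )


def select_model(candidates: Sequence[FitResult]) -> FitResult:
    """Pick the best candidate: lowest AIC, then highest R², then fewest params."""
    usable = [c for c in candidates if c.converged and np.isfinite(c.aic)]
    # RSS = 0 fits give aic -> -inf surrogate; keep them as strictly best
    exact = [c for c in candidates if c.converged and not np.isfinite(c.aic)
             and c.rss < 1e-290]
    usable += exact
    if not usable:
        raise FitError("no converged candidate to select from")
    return min(usable, key=lambda c: (c.aic, -c.r2, c.k))
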