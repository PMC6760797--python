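"""Cohort life tables from a compiled temperature-driven phenology model.

A phenology model bundles, for each immature stage (egg, nymph,
pre-adult), a development-rate curve, a lognormal development-time
variability, and a stage-mortality curve; plus adult female and male
senescence curves, a temperature–fecundity curve, a cumulative
oviposition curve over normalised adult age, and the female ratio.

From the model two routes lead to the demographic parameters:

* ``deterministic_schedule`` — the mean-field daily survivorship (lx) and
  daughter-fecundity (mx) schedule at a constant temperature;
* ``simulate_cohort`` — a stochastic cohort of individual eggs whose
  empirical schedule has the deterministic one as its expectation.

``life_table_params`` then yields the gross and net reproductive rates
(GRR, Ro), the intrinsic rate of increase rm (root of the Euler–Lotka
equation Σ e^{−rm·x}·lx·mx = 1), the mean generation time T, the finite
rate of increase λ = e^rm and the doubling time Dt = ln2/rm.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from . import thermal_models as tm

__all__ = [
    "StageModel",
    "PhenologyModel",
    "Schedule",
    "LifeTableParams",
    "build_phenology",
    "deterministic_schedule",
    "life_table_params",
    "simulate_cohort",
    "replicate_simulation",
    "solve_euler_lotka",
    "finite_rate_of_increase",
    "doubling_time",
    "mean_generation_time",
    "RM_NONVIABLE",
]

#: sentinel intrinsic rate for schedules with no reproduction (Ro = 0)
RM_NONVIABLE = float("-inf")

STAGE_ORDER = ("egg", "nymph", "pre_adult")


@dataclass(frozen=True)
class StageModel:
    """One immature stage: development curve, duration spread, mortality curve."""

    name: str
    development: object  # LinearDDParams | Logan1Params | AllahyariParams
    mortality: tm.WangMortalityParams
    sigma: float = 0.1  # lognormal sigma of individual development times

    def __post_init__(self):
        if self.sigma < 0:
            raise ValueError("sigma must be >= 0")


@dataclass(frozen=True)
class PhenologyModel:
    """The compiled set of stage-wise fitted curves driving the simulator."""

    stages: tuple  # ordered StageModel instances, egg first
    senescence_female: object
    senescence_male: object
    fecundity: tm.Wang7Params
    oviposition: tm.OvipositionCDFParams
    female_ratio: float = 0.5

    def __post_init__(self):
        if not 0.0 <= self.female_ratio <= 1.0:
            raise ValueError("female_ratio must lie in [0, 1]")
        if not self.stages:
            raise ValueError("at least one immature stage required")

    def stage_durations(self, T: float) -> Optional[list]:
        """Rounded stage durations (days) at T, or None if any rate is <= 0."""
        durations = []
        for st in self.stages:
            r = tm.development_rate(st.development, T)
            if r <= 0:
                return None
            durations.append(max(1, int(round(1.0 / r))))
        return durations

    def immature_survival(self, T: float) -> float:
        """Product over stages of (1 − stage mortality) at T."""
        s = 1.0
        for st in self.stages:
            s *= 1.0 - tm.eval_wang_mortality(st.mortality, T)
        return s


@dataclass
class Schedule:
    """Daily age-indexed survivorship and daughter-fecundity vectors.

    lx is survival from the egg to age x (lx[0] = 1, non-increasing); mx
    is daughter eggs per female at age x.  ``viable`` is False when no
    adult can be produced at this temperature within the horizon.
    """

    ages: np.ndarray
    lx: np.ndarray
    mx: np.ndarray
    temperature: float
    viable: bool = True
    adult_age: Optional[int] = None
    note: str = ""

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"age_day": self.ages, "lx": self.lx, "mx": self.mx})


@dataclass(frozen=True)
class LifeTableParams:
    """Demographic summary of one schedule."""

    rm: float        # intrinsic rate of increase, 1/day
    GRR: float       # gross reproductive rate, daughters/female
    Ro: float        # net reproductive rate, daughters/female
    T: float         # mean generation time, days
    lam: float       # finite rate of increase per day, e^rm
    Dt: float        # doubling time, days (inf when rm <= 0)

    def as_dict(self) -> dict:
        return {"rm": self.rm, "GRR": self.GRR, "Ro": self.Ro,
                "T": self.T, "lambda": self.lam, "Dt": self.Dt}


def build_phenology(components: dict, female_ratio: float = 0.5,
                    sigmas: Optional[dict] = None) -> PhenologyModel:
    """Assemble and validate a phenology model from per-process components.

    ``components`` maps process names to parameter sets (or FitResults,
    whose ``params`` attribute is taken): ``development_<stage>`` and
    ``mortality_<stage>`` for each stage in egg/nymph/pre_adult, plus
    ``fecundity``, ``oviposition``, ``senescence_female`` and
    ``senescence_male``.  Missing processes raise an error naming every gap.
    """
    def unwrap(v):
        return getattr(v, "params", v)

    required = [f"development_{s}" for s in STAGE_ORDER]
    required += [f"mortality_{s}" for s in STAGE_ORDER]
    required += ["fecundity", "oviposition", "senescence_female", "senescence_male"]
    missing = [k for k in required if components.get(k) is None]
    if missing:
        raise ValueError(f"phenology model incomplete, missing: {', '.join(missing)}")
    sigmas = sigmas or {}
    stages = tuple(
        StageModel(
            name=s,
            development=unwrap(components[f"development_{s}"]),
            mortality=unwrap(components[f"mortality_{s}"]),
            sigma=float(sigmas.get(s, 0.1)),
        )
        for s in STAGE_ORDER
    )
    return PhenologyModel(
        stages=stages,
        senescence_female=unwrap(components["senescence_female"]),
        senescence_male=unwrap(components["senescence_male"]),
        fecundity=unwrap(components["fecundity"]),
        oviposition=unwrap(components["oviposition"]),
        female_ratio=female_ratio,
    )


def deterministic_schedule(model: PhenologyModel, T: float,
                           horizon: int = 1500) -> Schedule:
    """Mean-field lx/mx schedule at constant temperature T.

    Stage durations are 1/r(T) rounded to whole days; survival drops by
    the stage mortality at each stage completion; adult females decay
    exponentially at the senescence rate; daughter eggs f(T)·female_ratio
    are allocated over adult ages by the oviposition CDF on age normalised
    by the mean adult lifespan 1/s(T).
    """
    ages = np.arange(horizon + 1)
    lx = np.ones(horizon + 1)
    mx = np.zeros(horizon + 1)

    durations = model.stage_durations(T)
    if durations is None or sum(durations) > horizon:
        note = ("non-positive development rate" if durations is None
                else "immature development exceeds horizon")
        return Schedule(ages=ages, lx=lx * 0 + 1, mx=mx, temperature=T,
                        viable=False, note=note)

    surv = 1.0
    age = 0
    for st, dur in zip(model.stages, durations):
        lx[age:age + dur] = surv
        surv *= 1.0 - tm.eval_wang_mortality(st.mortality, T)
        age += dur
    adult_age = age

    s = tm.eval_senescence(model.senescence_female, T)
    if s <= 0:
        # no senescence: adults persist to the horizon
        lx[adult_age:] = surv
        mean_life = float(horizon - adult_age)
    else:
        t_adult = np.arange(horizon + 1 - adult_age)
        lx[adult_age:] = surv * np.exp(-s * t_adult)
        mean_life = 1.0 / s

    f = tm.eval_wang7_fecundity(model.fecundity, T)
    if f > 0 and mean_life > 0:
        t = np.arange(horizon + 1 - adult_age)
        cdf = tm.eval_oviposition_cdf(model.oviposition, t / mean_life)
        inc = np.diff(cdf, append=cdf[-1])
        mx[adult_age:] = model.female_ratio * f * inc

    return Schedule(ages=ages, lx=lx, mx=mx, temperature=T,
                    viable=True, adult_age=adult_age)


def finite_rate_of_increase(rm: float) -> float:
    """λ = e^rm, the per-day multiplication factor of the population."""
    return math.exp(rm)


def doubling_time(rm: float) -> float:
    """Dt = ln2/rm days for a growing population, infinite otherwise."""
    return math.log(2.0) / rm if rm > 0 else float("inf")


def mean_generation_time(Ro: float, rm: float) -> float:
    """T = ln(Ro)/rm days (requires Ro > 0 and rm ≠ 0)."""
    return math.log(Ro) / rm


def _euler_lotka_residual(r, x, phi):
    # overflow at very negative trial rates just saturates to +inf, which
    # the bracketing logic treats correctly as "residual > 0"
    with np.errstate(over="ignore"):
        return np.sum(np.exp(-r * x) * phi) - 1.0


def solve_euler_lotka(ages: np.ndarray, lxmx: np.ndarray,
                      tol: float = 1e-12) -> float:
    """Root rm of Σ e^{−rm·x}·lx·mx = 1 by bisection on a widened bracket."""
    mask = lxmx > 0
    x, phi = ages[mask], lxmx[mask]
    # the residual is strictly decreasing in r (for reproduction past age 0),
    # positive at very negative r and negative at very positive r
    lo, hi = -1.0, 1.0
    for _ in range(200):
        if _euler_lotka_residual(lo, x, phi) > 0:
            break
        lo *= 2.0
    for _ in range(200):
        if _euler_lotka_residual(hi, x, phi) < 0:
            break
        hi *= 2.0
    flo = _euler_lotka_residual(lo, x, phi)
    fhi = _euler_lotka_residual(hi, x, phi)
    if not (flo > 0 > fhi):
        raise RuntimeError("Euler–Lotka bracket failed")
    # residual is decreasing in r: root where it crosses 0
    while hi - lo > tol:
        mid = 0.5 * (lo + hi)
        if _euler_lotka_residual(mid, x, phi) > 0:
            lo = mid
        else:
            hi = mid
    return 0.5 * (lo + hi)


def life_table_params(schedule: Schedule) -> LifeTableParams:
    """Demographic parameters of a schedule.

    Ro = Σ lx·mx and GRR = Σ mx; rm solves the Euler–Lotka equation when
    Ro > 0 and is the −inf sentinel otherwise; T = ln(Ro)/rm (the cohort
    mean generation age Σx·lx·mx/Ro when rm = 0); λ = e^rm; Dt = ln2/rm
    for growing populations, infinite otherwise.
    """
    lx, mx, ages = schedule.lx, schedule.mx, schedule.ages
    if np.any(np.diff(lx) > 1e-12):
        raise ValueError("lx must be non-increasing")
    if np.any(mx < 0):
        raise ValueError("mx must be non-negative")
    GRR = float(np.sum(mx))
    lxmx = lx * mx
    Ro = float(np.sum(lxmx))
    if Ro <= 0:
        return LifeTableParams(rm=RM_NONVIABLE, GRR=GRR, Ro=Ro,
                               T=float("nan"), lam=0.0, Dt=float("inf"))
    rm = solve_euler_lotka(ages.astype(float), lxmx)
    if rm != 0.0:
        T = mean_generation_time(Ro, rm)
    else:
        T = float(np.sum(ages * lxmx) / Ro)
    return LifeTableParams(rm=rm, GRR=GRR, Ro=Ro, T=T,
                           lam=finite_rate_of_increase(rm),
                           Dt=doubling_time(rm))


def simulate_cohort(
    model: PhenologyModel,
    T: float,
    n_eggs: int = 100,
    seed: int = 0,
    horizon: int = 1500,
    adult_lifespan: str = "stochastic",
):
    """Stochastic cohort of ``n_eggs`` female eggs at constant temperature T.

    Each individual draws per-stage Bernoulli survival from m(T), a
    lognormal stage duration with median 1/r(T) and the stage sigma, and
    an exponential adult lifespan at the female senescence rate (or the
    mean lifespan exactly, with ``adult_lifespan='fixed'``, which makes
    the cohort fully deterministic when every sigma is zero).  Daily
    daughter eggs follow the oviposition CDF increments × f(T) ×
    female_ratio while the female is alive.  Returns (Schedule,
    LifeTableParams) built from the empirical lx and per-capita mx.
    """
    if n_eggs < 1:
        raise ValueError("n_eggs must be >= 1")
    if adult_lifespan not in ("stochastic", "fixed"):
        raise ValueError("adult_lifespan must be 'stochastic' or 'fixed'")
    rng = np.random.default_rng(seed)
    ages = np.arange(horizon + 1)

    rates = [tm.development_rate(st.development, T) for st in model.stages]
    if any(r <= 0 for r in rates):
        lx = np.ones(horizon + 1)
        sched = Schedule(ages=ages, lx=lx, mx=np.zeros(horizon + 1),
                         temperature=T, viable=False,
                         note="non-positive development rate")
        return sched, life_table_params(sched)

    morts = [tm.eval_wang_mortality(st.mortality, T) for st in model.stages]
    s = tm.eval_senescence(model.senescence_female, T)
    f = tm.eval_wang7_fecundity(model.fecundity, T)

    alive = np.ones(n_eggs, dtype=bool)
    death_age = np.full(n_eggs, horizon + 1, dtype=float)
    age_now = np.zeros(n_eggs)
    for st, r, m in zip(model.stages, rates, morts):
        dur = (1.0 / r) * np.exp(st.sigma * rng.standard_normal(n_eggs))
        dur = np.maximum(1, np.round(dur))
        die = rng.random(n_eggs) < m
        newly_dead = alive & die
        # non-survivors die at a uniform fraction of their stage duration
        death_age[newly_dead] = (age_now[newly_dead]
                                 + np.ceil(rng.random(newly_dead.sum())
                                           * dur[newly_dead]))
        alive &= ~die
        age_now += dur
    emergence = age_now.copy()

    # normalised-age denominator: mean adult lifespan 1/s(T); with no
    # senescence the remaining horizon stands in (and the lifespan equals it)
    if s > 0:
        norm = np.full(n_eggs, 1.0 / s)
        if adult_lifespan == "fixed":
            lifespan = norm.copy()
        else:
            lifespan = rng.exponential(1.0 / s, n_eggs)
    else:
        norm = np.maximum(1.0, float(horizon) - emergence)
        lifespan = norm.copy()
    lifespan = np.maximum(1.0, np.round(lifespan))
    death_age[alive] = emergence[alive] + lifespan[alive]
    death_age = np.minimum(death_age, horizon + 1)

    lx = (death_age[None, :] > ages[:, None]).mean(axis=1)
    # per-capita daughter eggs among the cohort's founding females
    mx = np.zeros(horizon + 1)
    for i in np.nonzero(alive)[0]:
        a0 = int(min(emergence[i], horizon))
        a1 = int(min(death_age[i], horizon))
        if a1 <= a0:
            continue
        t = np.arange(a1 - a0 + 1)
        cdf = tm.eval_oviposition_cdf(model.oviposition, t / norm[i])
        eggs = model.female_ratio * f * np.diff(cdf)
        mx[a0:a1] += eggs
    # mx is daughters per founding female divided by survivorship -> per capita
    with np.errstate(invalid="ignore", divide="ignore"):
        mx_pc = np.where(lx > 0, mx / (n_eggs * np.maximum(lx, 1e-300)), 0.0)

    viable = bool(alive.any()) and np.all(emergence[alive] <= horizon)
    sched = Schedule(ages=ages, lx=lx, mx=mx_pc, temperature=T, viable=viable,
                     adult_age=int(emergence[alive].min()) if alive.any() else None)
    return sched, life_table_params(sched)


def replicate_simulation(
    model: PhenologyModel,
    temperatures: Sequence[float],
    n_eggs: int = 100,
    n_reps: int = 6,
    base_seed: int = 0,
    horizon: int = 1500,
) -> pd.DataFrame:
    """Replicated cohort simulations: mean ± SE per parameter per temperature.

    Seeds for the replicate runs are spawned deterministically from
    ``base_seed``, so the whole table is reproducible from one integer.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    ss = np.random.SeedSequence(base_seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(
        len(temperatures) * n_reps)]
    rows = []
    idx = 0
    for T in temperatures:
        reps = []
        for _ in range(n_reps):
            _, params = simulate_cohort(model, T, n_eggs=n_eggs,
                                        seed=seeds[idx], horizon=horizon)
            reps.append(params.as_dict())
            idx += 1
        frame = pd.DataFrame(reps)
        for name in ("rm", "GRR", "Ro", "T", "lambda", "Dt"):
            vals = frame[name].to_numpy(dtype=float)
            finite = vals[np.isfinite(vals)]
            if len(finite):
                mean = float(np.mean(finite))
                se = float(np.std(finite, ddof=1) / np.sqrt(len(finite))) \
                    if len(finite) > 1 else 0.0
            else:
                mean, se = float("nan"), float("nan")
            rows.append((float(T), name, mean, se, n_reps))
    return pd.DataFrame(rows, columns=["temperature_c", "parameter",
                                       "mean", "se", "n_reps"])
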