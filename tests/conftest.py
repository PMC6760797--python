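import numpy as np
import pytest

from phenotherm import datasets
from phenotherm import thermal_models as tm
from phenotherm.life_table import PhenologyModel, StageModel


@pytest.fixture(scope="session")
def ref_params():
    return datasets.reference_params()


@pytest.fixture(scope="session")
def ref_model():
    return datasets.reference_model()


@pytest.fixture(scope="session")
def degenerate_model(ref_model):
    """Reference model with all randomness switched off.

    Stage mortalities are made negligible (H -> 0+), development-time
    spread is zero, and the female senescence curve is placed so its rate
    clips to zero over the working range; adults then live exactly to the
    horizon and a stochastic cohort reproduces the deterministic schedule.
    """
    stages = tuple(
        StageModel(
            name=s.name,
            development=s.development,
            mortality=tm.WangMortalityParams(
                variant=s.mortality.variant, B=s.mortality.B, H=1e-12,
                Tl=s.mortality.Tl, Th=s.mortality.Th, Topt=s.mortality.Topt),
            sigma=0.0,
        )
        for s in ref_model.stages
    )
    flat_senescence = tm.HilbertLogan3Params(trid=0.05, Tmin=0.0, Tmax=5.0,
                                             D=1e6, Dt=5.0)
    return PhenologyModel(
        stages=stages,
        senescence_female=flat_senescence,
        senescence_male=ref_model.senescence_male,
        fecundity=ref_model.fecundity,
        oviposition=ref_model.oviposition,
        female_ratio=0.5,
    )


@pytest.fixture()
def rng():
    return np.random.default_rng(20260928)


def random_schedule(rng, max_len=60):
    """A random valid lx/mx schedule whose growth rate lies inside (-1, 1).

    Reproduction starts at age >= 8 with bounded daily fecundity, which
    caps the Euler-Lotka root well below 1/day while keeping it above
    -1/day (the residual at -1 always exceeds 1 for any reproduction).
    """
    from phenotherm.life_table import Schedule

    n = int(rng.integers(12, max_len))
    ages = np.arange(n)
    lx = np.cumprod(np.concatenate([[1.0], rng.uniform(0.8, 1.0, n - 1)]))
    mx = np.zeros(n)
    start = int(rng.integers(8, n - 1))
    mx[start:] = rng.uniform(0.0, 2.0, n - start)
    if mx[start:].sum() == 0:
        mx[start] = 1.0
    return Schedule(ages=ages, lx=lx, mx=mx, temperature=25.0)
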