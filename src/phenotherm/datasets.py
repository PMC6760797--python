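"""Bundled reference data for the African edible cricket *Scapsipedus icipe*.

Three small summary tables from published constant-temperature rearing
experiments (mean stage-development times, reproduction and adult
longevity, and simulated life-table parameters), plus a stage-keyed
parameter bundle.  In the bundle the development curves and linear
degree-day coefficients are published estimates; the fecundity and
senescence curves are least-squares fits of this package to the summary
means; the stage-mortality curves are synthetic stand-ins (the published
fits are not available) chosen to be consistent with the reported
viability limits — no hatch at 10 or 40 °C, full development at 20–37 °C.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from . import thermal_models as tm
from .life_table import PhenologyModel, build_phenology

__all__ = [
    "load_development_times",
    "load_reproduction_longevity",
    "load_life_table_reference",
    "reference_params",
    "reference_model",
]


def _data_path(name: str):
    return resources.files("phenotherm.data") / name


def load_development_times() -> pd.DataFrame:
    """Mean (±SE) stage development times (days) per constant temperature.

    The ``nymph`` rows are the pooled sums of the published per-instar
    means, matching the pooled egg / nymph / pre-adult fitting stages.
    """
    with resources.as_file(_data_path("development_times.csv")) as p:
        return pd.read_csv(p)


def load_reproduction_longevity() -> pd.DataFrame:
    """Lifetime fecundity, oviposition periods and adult longevities."""
    with resources.as_file(_data_path("reproduction_longevity.csv")) as p:
        return pd.read_csv(p)


def load_life_table_reference() -> pd.DataFrame:
    """Published cohort-simulation life-table parameters per temperature."""
    with resources.as_file(_data_path("life_table_reference.csv")) as p:
        return pd.read_csv(p)


def reference_params() -> dict:
    """The bundled stage-keyed parameter sets (see module docstring)."""
    with resources.as_file(_data_path("scapsipedus_params.json")) as p:
        return tm.load_param_bundle(p)


def reference_model(female_ratio: float = 0.5, sigma: float = 0.1) -> PhenologyModel:
    """The bundled parameters compiled into a ready-to-run phenology model."""
    params = reference_params()
    components = {k: v for k, v in params.items() if not k.startswith("linear_")}
    sigmas = {s: sigma for s in ("egg", "nymph", "pre_adult")}
    return build_phenology(components, female_ratio=female_ratio, sigmas=sigmas)
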