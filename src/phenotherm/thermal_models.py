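"""Parametric temperature-response curves for insect phenology.

Every temperature-driven process in the life cycle — immature development,
stage mortality, lifetime fecundity, age-structured oviposition and adult
senescence — is described by a small parametric curve of temperature (°C
throughout; no Kelvin anywhere).  This module defines the parameter
containers, vectorised evaluators, and extraction of the cardinal thermal
thresholds (lower threshold ``Tmin``, optimum ``Topt``, upper limit
``Tmax``, and the degree-day constant ``K`` for the linear model).

The curve families are

* linear degree-day model            r(T) = a + b·T
* Logan 1                            r(T) = Y·(e^{pT} − e^{p·Tmax − (Tmax−T)/v})
* Allahyari                          r(T) = P·xⁿ·(1 − xᵐ),  x = (T−Tmin)/(Tmax−Tmin)
* Wang mortality (two-sided)         m(T) = 1 − exp(−H·(1+e^{−(T−Tl)/B})·(1+e^{−(Th−T)/B}))
* Wang mortality (symmetric)         as above with Topt substituted for Tl and Th
* Wang 7 fecundity                   double logistic, normalised so f(Topt) = Fmax
* exponential cumulative oviposition O(E) = 1 − exp(−(aE + bE² + cE³))
* Hilbert–Logan 3 senescence         s(T) = trid·((T−Tmin)²/((T−Tmin)²+D) − e^{−(Tmax−(T−Tmin))/Dt})
* exponential-simple senescence      s(T) = b1·e^{b2·T}

Development and senescence rates are per day; mortality is a per-stage
fraction in [0, 1]; fecundity is lifetime eggs per female.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, asdict, fields
from pathlib import Path
from typing import Optional, Union

import numpy as np
from scipy.optimize import brentq, minimize_scalar

__all__ = [
    "LinearDDParams",
    "Logan1Params",
    "AllahyariParams",
    "WangMortalityParams",
    "Wang7Params",
    "OvipositionCDFParams",
    "HilbertLogan3Params",
    "ExpSimpleParams",
    "ThermalThresholds",
    "ThresholdUndefinedError",
    "eval_linear",
    "eval_logan1",
    "eval_allahyari",
    "eval_wang_mortality",
    "eval_wang7_fecundity",
    "eval_oviposition_cdf",
    "eval_senescence",
    "development_rate",
    "thresholds_from_model",
    "params_to_dict",
    "params_from_dict",
    "load_param_bundle",
    "save_param_bundle",
]

SCHEMA_VERSION = 1


class ThresholdUndefinedError(ValueError):
    """Raised when a cardinal temperature cannot be extracted from a model."""


def _as_array(T):
    arr = np.asarray(T, dtype=float)
    return arr, arr.ndim == 0


def _maybe_scalar(values, scalar):
    return float(values) if scalar else values


@dataclass(frozen=True)
class LinearDDParams:
    """Linear degree-day model: intercept ``a`` and slope ``b`` (rate/day/°C).

    The lower developmental threshold is the root −a/b and the thermal
    constant (degree-days to complete the stage) is 1/b.
    """

    a: float
    b: float


@dataclass(frozen=True)
class Logan1Params:
    """Logan 1 development-rate curve.

    Y is a scale (rate/day), p the exponential rate coefficient (1/°C),
    Tmax the upper lethal temperature (°C) where the rate vanishes, and v
    the width (°C) of the high-temperature boundary layer.
    """

    Y: float
    p: float
    Tmax: float
    v: float

    def __post_init__(self):
        if self.Y < 0 or self.v <= 0 or self.Tmax <= 0:
            raise ValueError("Logan 1 requires Y >= 0, v > 0, Tmax > 0")


@dataclass(frozen=True)
class AllahyariParams:
    """Allahyari development-rate curve on the normalised temperature x."""

    P: float
    Tmin: float
    Tmax: float
    n: float
    m: float

    def __post_init__(self):
        if self.Tmax <= self.Tmin:
            raise ValueError("Allahyari requires Tmax > Tmin")
        if self.P <= 0 or self.n <= 0 or self.m <= 0:
            raise ValueError("Allahyari requires P, n, m > 0")


@dataclass(frozen=True)
class WangMortalityParams:
    """Wang stage-mortality curve, two-sided (Tl, Th) or symmetric (Topt).

    The two-sided variant is U-shaped between the lower (Tl) and upper (Th)
    lethal temperatures; the symmetric variant substitutes the optimal
    survival temperature Topt on both flanks and attains its minimum
    1 − e^{−4H} exactly there.  B is the flank width (°C) and H the depth.
    """

    variant: str  # "two_sided" | "symmetric"
    B: float
    H: float
    Tl: Optional[float] = None
    Th: Optional[float] = None
    Topt: Optional[float] = None

    def __post_init__(self):
        if self.variant not in ("two_sided", "symmetric"):
            raise ValueError(f"unknown Wang mortality variant {self.variant!r}")
        if self.B <= 0 or self.H <= 0:
            raise ValueError("Wang mortality requires B > 0 and H > 0")
        if self.variant == "two_sided":
            if self.Tl is None or self.Th is None or self.Th <= self.Tl:
                raise ValueError("two-sided Wang mortality requires Th > Tl")
        else:
            if self.Topt is None:
                raise ValueError("symmetric Wang mortality requires Topt")


@dataclass(frozen=True)
class Wang7Params:
    """Wang 7 temperature–fecundity curve.

    Product of two opposing logistics in (T−Topt)/B1 and (Topt−T)/Bh,
    normalised so that f(Topt) = Fmax lifetime eggs per female; H is a
    shape exponent on the normalised product (1 leaves the plain product).
    """

    Fmax: float
    Topt: float
    B1: float
    Bh: float
    H: float = 1.0

    def __post_init__(self):
        if self.Fmax <= 0 or self.B1 <= 0 or self.Bh <= 0 or self.H <= 0:
            raise ValueError("Wang 7 requires Fmax, B1, Bh, H > 0")


@dataclass(frozen=True)
class OvipositionCDFParams:
    """Cumulative oviposition over normalised adult age E.

    O(E) = 1 − exp(−(aE + bE² + cE³)); E is adult age in days divided by
    the mean adult survival time at the same temperature.  The cubic
    exponent must produce a non-decreasing CDF on the working domain,
    which is validated numerically at construction.
    """

    a: float
    b: float
    c: float

    def __post_init__(self):
        E = np.linspace(0.0, 3.0, 601)
        o = eval_oviposition_cdf(self, E)
        if np.any(np.diff(o) < -1e-12):
            raise ValueError("oviposition CDF is decreasing on [0, 3]")


@dataclass(frozen=True)
class HilbertLogan3Params:
    """Hilbert–Logan 3 adult senescence-rate curve (1/day)."""

    trid: float
    Tmin: float
    Tmax: float
    D: float
    Dt: float

    def __post_init__(self):
        if self.trid <= 0 or self.D <= 0 or self.Dt <= 0:
            raise ValueError("Hilbert–Logan 3 requires trid, D, Dt > 0")


@dataclass(frozen=True)
class ExpSimpleParams:
    """Exponential-simple senescence: s(T) = b1·exp(b2·T)."""

    b1: float
    b2: float

    def __post_init__(self):
        if self.b1 <= 0:
            raise ValueError("exponential-simple requires b1 > 0")


@dataclass(frozen=True)
class ThermalThresholds:
    """Cardinal temperatures of a development model (°C; K in degree-days)."""

    Tmin: Optional[float] = None
    Topt: Optional[float] = None
    Tmax: Optional[float] = None
    K: Optional[float] = None


DevelopmentParams = Union[LinearDDParams, Logan1Params, AllahyariParams]
SenescenceParams = Union[HilbertLogan3Params, ExpSimpleParams]


def _clip_rate(raw, clip):
    if not clip:
        return raw
    return np.maximum(raw, 0.0)


def eval_linear(params: LinearDDParams, T, clip: bool = True):
    """Linear degree-day rate a + b·T, clipped at 0 when used as a rate."""
    arr, scalar = _as_array(T)
    raw = params.a + params.b * arr
    return _maybe_scalar(_clip_rate(raw, clip), scalar)


def eval_logan1(params: Logan1Params, T, clip: bool = True):
    """Logan 1 rate Y·(e^{pT} − e^{p·Tmax − (Tmax−T)/v}); exactly 0 at Tmax."""
    arr, scalar = _as_array(T)
    raw = params.Y * (
        np.exp(params.p * arr)
        - np.exp(params.p * params.Tmax - (params.Tmax - arr) / params.v)
    )
    return _maybe_scalar(_clip_rate(raw, clip), scalar)


def eval_allahyari(params: AllahyariParams, T, clip: bool = True):
    """Allahyari rate P·xⁿ·(1−xᵐ) on x=(T−Tmin)/(Tmax−Tmin); 0 outside [Tmin, Tmax]."""
    arr, scalar = _as_array(T)
    x = (arr - params.Tmin) / (params.Tmax - params.Tmin)
    inside = (x >= 0.0) & (x <= 1.0)
    xs = np.where(inside, x, 0.5)  # dummy inside value avoids power warnings
    raw = np.where(inside, params.P * xs**params.n * (1.0 - xs**params.m), 0.0)
    return _maybe_scalar(_clip_rate(raw, clip), scalar)


def eval_wang_mortality(params: WangMortalityParams, T):
    """Wang stage mortality in [0, 1]; U-shaped (two-sided) or symmetric in Topt."""
    arr, scalar = _as_array(T)
    if params.variant == "two_sided":
        lo, hi = params.Tl, params.Th
    else:
        lo = hi = params.Topt
    # exponent capped to avoid overflow far outside the lethal bounds
    left = 1.0 + np.exp(np.minimum((lo - arr) / params.B, 700.0))
    right = 1.0 + np.exp(np.minimum((arr - hi) / params.B, 700.0))
    m = 1.0 - np.exp(-params.H * left * right)
    return _maybe_scalar(np.clip(m, 0.0, 1.0), scalar)


def eval_wang7_fecundity(params: Wang7Params, T):
    """Wang 7 lifetime fecundity (eggs/female); equals Fmax at Topt."""
    arr, scalar = _as_array(T)
    L1 = 1.0 / (1.0 + np.exp(np.minimum(-(arr - params.Topt) / params.B1, 700.0)))
    L2 = 1.0 / (1.0 + np.exp(np.minimum(-(params.Topt - arr) / params.Bh, 700.0)))
    f = params.Fmax * (4.0 * L1 * L2) ** params.H
    return _maybe_scalar(f, scalar)


def eval_oviposition_cdf(params: OvipositionCDFParams, E):
    """Cumulative fraction of lifetime eggs laid by normalised adult age E."""
    arr, scalar = _as_array(E)
    if np.any(arr < 0):
        raise ValueError("normalised age E must be >= 0")
    expo = params.a * arr + params.b * arr**2 + params.c * arr**3
    o = 1.0 - np.exp(-expo)
    return _maybe_scalar(np.clip(o, 0.0, 1.0), scalar)


def eval_senescence(params: SenescenceParams, T, clip: bool = True):
    """Adult senescence rate (1/day) under either senescence family."""
    arr, scalar = _as_array(T)
    if isinstance(params, ExpSimpleParams):
        raw = params.b1 * np.exp(params.b2 * arr)
    elif isinstance(params, HilbertLogan3Params):
        u = arr - params.Tmin
        raw = params.trid * (
            u**2 / (u**2 + params.D) - np.exp(-(params.Tmax - u) / params.Dt)
        )
    else:
        raise TypeError(f"not a senescence parameter set: {type(params).__name__}")
    return _maybe_scalar(_clip_rate(raw, clip), scalar)


def development_rate(params: DevelopmentParams, T, clip: bool = True):
    """Dispatch a development-rate evaluation for any of the three families."""
    if isinstance(params, LinearDDParams):
        return eval_linear(params, T, clip=clip)
    if isinstance(params, Logan1Params):
        return eval_logan1(params, T, clip=clip)
    if isinstance(params, AllahyariParams):
        return eval_allahyari(params, T, clip=clip)
    raise TypeError(f"not a development parameter set: {type(params).__name__}")


def _bounded_argmax(fun, lo, hi):
    res = minimize_scalar(lambda t: -fun(t), bounds=(lo, hi), method="bounded",
                          options={"xatol": 1e-8})
    return float(res.x), float(-res.fun)


def thresholds_from_model(model: DevelopmentParams) -> ThermalThresholds:
    """Extract the cardinal temperatures of a development model.

    Linear: Tmin = −a/b and K = 1/b (degree-days).  Allahyari: Tmin and
    Tmax are parameters, Topt is the bounded maximiser of the rate.
    Logan 1: Tmax is a parameter, Topt the bounded maximiser, Tmin the
    lower zero-crossing of the raw rate on (0, Topt) — reported as None
    when the curve never crosses zero there.
    """
    if isinstance(model, LinearDDParams):
        if model.b == 0:
            raise ThresholdUndefinedError("linear model with zero slope")
        return ThermalThresholds(Tmin=-model.a / model.b, K=1.0 / model.b)
    if isinstance(model, AllahyariParams):
        topt, peak = _bounded_argmax(lambda t: eval_allahyari(model, t),
                                     model.Tmin, model.Tmax)
        if peak <= 0:
            raise ThresholdUndefinedError("flat Allahyari curve")
        return ThermalThresholds(Tmin=model.Tmin, Topt=topt, Tmax=model.Tmax)
    if isinstance(model, Logan1Params):
        topt, peak = _bounded_argmax(lambda t: eval_logan1(model, t, clip=False),
                                     0.0, model.Tmax)
        if peak <= 0:
            raise ThresholdUndefinedError("flat Logan 1 curve")
        f0 = eval_logan1(model, 0.0, clip=False)
        tmin = None
        if f0 < 0:
            tmin = float(brentq(lambda t: eval_logan1(model, t, clip=False),
                                0.0, topt, xtol=1e-10))
        return ThermalThresholds(Tmin=tmin, Topt=topt, Tmax=model.Tmax)
    raise TypeError(f"not a development parameter set: {type(model).__name__}")


# ---------------------------------------------------------------------------
# JSON (de)serialisation of parameter sets and stage-keyed bundles

_FAMILIES = {
    "linear": LinearDDParams,
    "logan1": Logan1Params,
    "allahyari": AllahyariParams,
    "wang_mortality": WangMortalityParams,
    "wang7": Wang7Params,
    "oviposition_cdf": OvipositionCDFParams,
    "hilbert_logan3": HilbertLogan3Params,
    "exp_simple": ExpSimpleParams,
}
_FAMILY_OF = {cls: name for name, cls in _FAMILIES.items()}


def params_to_dict(params) -> dict:
    """Serialise a parameter set to a plain dict tagged with its family."""
    family = _FAMILY_OF.get(type(params))
    if family is None:
        raise TypeError(f"unknown parameter type {type(params).__name__}")
    d = {"family": family}
    d.update(asdict(params))
    return d


def params_from_dict(d: dict):
    """Rebuild a parameter set from its tagged dict form."""
    d = dict(d)
    family = d.pop("family")
    cls = _FAMILIES.get(family)
    if cls is None:
        raise ValueError(f"unknown model family {family!r}")
    names = {f.name for f in fields(cls)}
    kwargs = {k: v for k, v in d.items() if k in names and v is not None}
    return cls(**kwargs)


def save_param_bundle(bundle: dict, path) -> None:
    """Write a stage-keyed bundle of parameter sets as JSON."""
    doc = {"schema_version": SCHEMA_VERSION, "models": {}}
    for key, value in bundle.items():
        if isinstance(value, dict):
            doc["models"][key] = {k: params_to_dict(v) for k, v in value.items()}
        else:
            doc["models"][key] = params_to_dict(value)
    Path(path).write_text(json.dumps(doc, indent=2, sort_keys=True) + "\n")


def load_param_bundle(path) -> dict:
    """Read a stage-keyed JSON parameter bundle written by save_param_bundle."""
    doc = json.loads(Path(path).read_text())
    version = doc.get("schema_version")
    if version != SCHEMA_VERSION:
        raise ValueError(f"unsupported parameter schema version {version!r}")
    out = {}
    for key, value in doc["models"].items():
        if "family" in value:
            out[key] = params_from_dict(value)
        else:
            out[key] = {k: params_from_dict(v) for k, v in value.items()}
    return out
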