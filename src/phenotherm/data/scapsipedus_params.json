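{
  "models": {
    "development_egg": {
      "Tmax": 39.537,
      "Y": 0.002,
      "family": "logan1",
      "p": 0.199,
      "v": 4.7
    },
    "development_nymph": {
      "P": 1.846,
      "Tmax": 43.468,
      "Tmin": 13.081,
      "family": "allahyari",
      "m": 0.073,
      "n": 2.593
    },
    "development_pre_adult": {
      "P": 12.804,
      "Tmax": 39.168,
      "Tmin": 16.113,
      "family": "allahyari",
      "m": 0.408,
      "n": 3.793
    },
    "fecundity": {
      "B1": 2.3231,
      "Bh": 1.6955,
      "Fmax": 3393.054,
      "H": 1.0,
      "Topt": 30.0,
      "family": "wang7"
    },
    "linear_egg": {
      "a": -0.077,
      "b": 0.005,
      "family": "linear"
    },
    "linear_nymph": {
      "a": -0.011,
      "b": 0.0009,
      "family": "linear"
    },
    "linear_pre_adult": {
      "a": -0.47,
      "b": 0.025,
      "family": "linear"
    },
    "mortality_egg": {
      "B": 0.45,
      "H": 0.03,
      "Th": 37.5,
      "Tl": 13.5,
      "Topt": null,
      "family": "wang_mortality",
      "variant": "two_sided"
    },
    "mortality_nymph": {
      "B": 1.0,
      "H": 0.04,
      "Th": 39.5,
      "Tl": 16.5,
      "Topt": null,
      "family": "wang_mortality",
      "variant": "two_sided"
    },
    "mortality_pre_adult": {
      "B": 2.5,
      "H": 0.004,
      "Th": null,
      "Tl": null,
      "Topt": 30.0,
      "family": "wang_mortality",
      "variant": "symmetric"
    },
    "oviposition": {
      "a": 0.3,
      "b": 1.7,
      "c": 0.3,
      "family": "oviposition_cdf"
    },
    "senescence_female": {
      "D": 5000.0,
      "Dt": 0.4175,
      "Tmax": 50.875,
      "Tmin": 5.066,
      "family": "hilbert_logan3",
      "trid": 0.2034
    },
    "senescence_male": {
      "b1": 0.0014554,
      "b2": 0.080745,
      "family": "exp_simple"
    }
  },
  "schema_version": 1
}
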