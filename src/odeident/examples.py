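"""Bundled example models: three bioengineering case studies plus static toys.

* ``model1`` — two-state mRNA/protein regulation (transcription k1, mRNA
  degradation k2, translation k3, protein degradation k4); linear, both
  states observable, ICs mRNA(0)=2.5 and Protein(0)=6.5 (a.u.).
* ``model2`` — three-state perfusion bioreactor (glucose, lactate, cell
  concentration) with Monod growth, lactate inhibition, dilution rate D_r
  and feed glucose GF as known constants; all states observed.
* ``model3`` — two-state erythroblast growth inhibition with a sigmoidal
  exponential inhibition term; only the cell concentration X is observed.
  The ``augmented`` form polynomialises the exponential by a new state
  phi = exp(a*I) and parameter r_ab = exp(-a*b), so the rank test applies.
* toys ``y=2a``, ``y=2a^2``, ``y=a+b`` — dynamics-free calibration cases
  for the identifiability classifiers (global / local with 2 solutions /
  unidentifiable).

All constructors parse plain-text configs through the model parser, so
every fixture is validated and serialisable.
"""

from __future__ import annotations

from .model import OdeModel, parse_model

__all__ = [
    "model1",
    "model2",
    "model3",
    "toy",
    "get_model",
    "reference_params",
    "REGISTRY",
]

_MODEL1 = """\
name: model1
states: [mRNA, Protein]
parameters: [k1, k2, k3, k4]
odes:
  mRNA: k1 - k2*mRNA
  Protein: k3*mRNA - k4*Protein
outputs:
  mRNA: mRNA
  Protein: Protein
init:
  mRNA: 2.5
  Protein: 6.5
units:
  mRNA: a.u.
  Protein: a.u.
"""

_MODEL2 = """\
name: model2
states: [Glucose, Lactate, X]
parameters: [r_glu, r_lac, mu_max, km_glu, ki_lac]
constants:
  D_r: {D_r}
  GF: {GF}
odes:
  Glucose: D_r*(GF - Glucose) - r_glu*X
  Lactate: -D_r*Lactate + r_lac*X
  X: ((mu_max*Glucose/(km_glu + Glucose))*(ki_lac/(ki_lac + Lactate^2)) - D_r)*X
outputs:
  Glucose: Glucose
  Lactate: Lactate
  X: X
init:
  Glucose: 1.01
  Lactate: 3.98
  X: 0.46
units:
  Glucose: mM
  Lactate: mM
  X: cells x10^6/mL
  D_r: hr^-1
  GF: mM
"""

_MODEL3_ORIGINAL = """\
name: model3
states: [X, I]
parameters: [r_g, r_d, a, b]
odes:
  X: r_g*X/(1 + exp(a*(I - b)))
  I: r_g*X/(1 + exp(a*(I - b))) - r_d*I
outputs:
  X: X
init:
  X: 4.45
  I: 0.0
units:
  X: cells x10^6/mL
  I: cells x10^6/mL
"""

# the growth-inhibition model as first published, with the exponent
# reversed (a*(b - I)); kept for comparison only
_MODEL3_ORIGINAL_SIGN = """\
name: model3_original_sign
states: [X, I]
parameters: [r_g, r_d, a, b]
odes:
  X: r_g*X/(1 + exp(a*(b - I)))
  I: r_g*X/(1 + exp(a*(b - I))) - r_d*I
outputs:
  X: X
init:
  X: 4.45
  I: 0.0
"""

_MODEL3_AUGMENTED = """\
name: model3_augmented
states: [X, I, phi]
parameters: [r_g, r_d, a, r_ab]
odes:
  X: r_g*X/(1 + r_ab*phi)
  I: r_g*X/(1 + r_ab*phi) - r_d*I
  phi: phi*a*(r_g*X/(1 + r_ab*phi) - r_d*I)
outputs:
  X: X
init:
  X: 4.45
  I: 0.0
  phi: 1.0
units:
  phi: a.u.
"""

_TOYS = {
    "y=2a": """\
name: toy_2a
states: []
parameters: [a]
odes: {}
outputs:
  y: 2*a
init: {}
""",
    "y=2a^2": """\
name: toy_2a2
states: []
parameters: [a]
odes: {}
outputs:
  y: 2*a^2
init: {}
""",
    "y=a+b": """\
name: toy_a_plus_b
states: []
parameters: [a, b]
odes: {}
outputs:
  y: a + b
init: {}
""",
}

#: constants for model 2 as published vs re-estimated against the time courses
MODEL2_CONSTANTS = {
    "original": {"D_r": 0.033, "GF": 7.0},
    "reestimated": {"D_r": 0.017, "GF": 0.131},
}


def model1(outputs: str = "both") -> OdeModel:
    """Two-state mRNA/protein model; ``outputs`` picks the observation set.

    Scenarios: ``both`` (m=2), ``mrna_only``, ``protein_only``.  The
    mRNA-only scenario is the classic structurally unidentifiable case
    (k3 and k4 leave no trace in the mRNA time course).
    """
    model = parse_model(_MODEL1)
    scenarios = {
        "both": ["mRNA", "Protein"],
        "mrna_only": ["mRNA"],
        "protein_only": ["Protein"],
    }
    if outputs not in scenarios:
        raise ValueError(f"unknown scenario '{outputs}'; choose from {list(scenarios)}")
    return model.with_outputs(scenarios[outputs])


def model2(constants: str = "reestimated") -> OdeModel:
    """Three-state bioreactor model with known dilution/feed constants.

    ``constants="original"`` uses the published D_r = 0.033 /hr and
    GF = 7 mM; ``"reestimated"`` uses D_r = 0.017 /hr, GF = 0.131 mM —
    the values re-estimated against the time-course data (the published
    pair drives simulated glucose negative on this dataset).
    """
    if constants not in MODEL2_CONSTANTS:
        raise ValueError(
            f"unknown constant set '{constants}'; choose from {list(MODEL2_CONSTANTS)}"
        )
    c = MODEL2_CONSTANTS[constants]
    return parse_model(_MODEL2.format(D_r=c["D_r"], GF=c["GF"]))


def model3(form: str = "augmented") -> OdeModel:
    """Erythroblast growth-inhibition model; only X observed.

    Forms: ``original`` (exponential inhibition, unknowns {r_g, r_d, a,
    b}), ``augmented`` (polynomialised: extra unobserved state phi with
    phi(0) = exp(a*I(0)) = 1, parameter r_ab = exp(-a*b) replacing b),
    and ``original_sign`` (the exponent as first published, a*(b - I);
    provided for reference only).
    """
    forms = {
        "original": _MODEL3_ORIGINAL,
        "augmented": _MODEL3_AUGMENTED,
        "original_sign": _MODEL3_ORIGINAL_SIGN,
    }
    if form not in forms:
        raise ValueError(f"unknown form '{form}'; choose from {list(forms)}")
    return parse_model(forms[form])


def toy(name: str) -> OdeModel:
    """Dynamics-free calibration models ``y=2a``, ``y=2a^2``, ``y=a+b``."""
    if name not in _TOYS:
        raise ValueError(f"unknown toy '{name}'; choose from {list(_TOYS)}")
    return parse_model(_TOYS[name])


REGISTRY = {
    "model1": model1,
    "model2": model2,
    "model3": model3,
    "toy": toy,
}


def get_model(name: str, **kwargs) -> OdeModel:
    """Look up a bundled model constructor by name and build it."""
    if name not in REGISTRY:
        raise ValueError(f"unknown model '{name}'; choose from {list(REGISTRY)}")
    return REGISTRY[name](**kwargs)


#: reference parameter points used for simulation demos and synthetic data
_REFERENCE = {
    "model1": {"k1": 0.25, "k2": 0.5, "k3": 0.25, "k4": 0.5},
    "model2": {
        "r_glu": 0.032,
        "r_lac": 0.020,
        "mu_max": 0.078,
        "km_glu": 0.221,
        "ki_lac": 10.954,
    },
    "model3": {"r_g": 0.057, "r_d": 0.005, "a": 2.6, "b": 3.4},
}


def reference_params(name: str) -> dict:
    """Reference parameter point for a bundled model.

    For ``model3`` the point covers the original parameterisation; the
    augmented form's r_ab follows as exp(-a*b).
    """
    import math

    if name in _REFERENCE:
        return dict(_REFERENCE[name])
    if name == "model3_augmented":
        p = dict(_REFERENCE["model3"])
        p["r_ab"] = math.exp(-p.pop("a") * p.pop("b"))
        p["a"] = _REFERENCE["model3"]["a"]
        return p
    raise ValueError(f"no reference parameters for '{name}'")
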