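import numpy as np
import pytest

import odeident as oi


@pytest.fixture(scope="session")
def m1_both():
    return oi.model1("both")


@pytest.fixture(scope="session")
def m1_mrna():
    return oi.model1("mrna_only")


@pytest.fixture(scope="session")
def m2():
    return oi.model2()


@pytest.fixture(scope="session")
def m3_aug():
    return oi.model3("augmented")


@pytest.fixture(scope="session")
def p1():
    return oi.reference_params("model1")


@pytest.fixture(scope="session")
def model1_data(m1_both, p1):
    """Noisy synthetic model-1 time courses at the preset design."""
    design = oi.case_study_designs()["model1_like"]
    return oi.generate(m1_both, p1, design, seed=11)


@pytest.fixture(scope="session")
def model1_fit(m1_both, p1, model1_data):
    return oi.fit(m1_both, model1_data, init=p1, n_starts=1)


def random_linear_2state(rng: np.random.Generator):
    """Random 2-state linear compartmental model, single observed state.

    dx1/dt = -(a01 + a21) x1 + a12 x2 (+ u), dx2/dt = a21 x1 - (a02 + a12) x2,
    with a random subset of the four rate parameters present.
    """
    import odeident as oi

    present = rng.integers(0, 2, size=4)
    while present.sum() == 0:
        present = rng.integers(0, 2, size=4)
    names = ["a01", "a21", "a12", "a02"]
    params = [n for n, keep in zip(names, present) if keep]
    term = {n: (n if n in params else "0") for n in names}
    cfg = f"""
name: rand2
states: [x1, x2]
parameters: [{", ".join(params)}]
odes:
  x1: -({term["a01"]} + {term["a21"]})*x1 + {term["a12"]}*x2
  x2: {term["a21"]}*x1 - ({term["a02"]} + {term["a12"]})*x2
outputs:
  y: x1
init:
  x1: {rng.integers(1, 5)}
  x2: {rng.integers(1, 5)}
"""
    return oi.parse_model(cfg)
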