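import numpy as np
import pytest

import clonesim as cs


@pytest.fixture(scope="session")
def pa_model():
    """Canonical population-asymmetry model: lam=1, r=0.25, gamma=1."""
    return cs.canonical("PA", lam=1.0, r=0.25, gamma=1.0)


@pytest.fixture(scope="session")
def pa_ensemble(pa_model):
    """20,000 PA clones from one S cell to t=100 (long-time GPA regime);
    shared by the variance, surviving-mean and exponential-law checks."""
    return cs.simulate_ensemble(
        pa_model, 20_000, "S", cs.StoppingRule("fixed_time", t_max=100.0), seed=20_260_101
    )


@pytest.fixture(scope="session")
def gia0_model():
    return cs.canonical("GIA0", lam1=1.0, lam2=0.5, gamma=1.0)


def random_small_model(rng: np.random.Generator) -> cs.CellFateModel:
    """Small random (not necessarily homeostatic) model for algebraic
    property tests."""
    m = int(rng.integers(1, 5))
    states = [f"X{i+1}" for i in range(m)]
    divisions = {}
    for i in range(m):
        if rng.random() < 0.7:
            n_pairs = int(rng.integers(1, 4))
            probs = rng.dirichlet(np.ones(n_pairs))
            outs = [
                ((states[int(rng.integers(m))], states[int(rng.integers(m))]), float(p))
                for p in probs
            ]
            divisions[states[i]] = (float(rng.uniform(0.05, 2.0)), outs)
    transitions = [
        (states[i], states[j], float(rng.uniform(0.05, 2.0)))
        for i in range(m)
        for j in range(m)
        if i != j and rng.random() < 0.4
    ]
    losses = {
        states[i]: float(rng.uniform(0.05, 2.0)) for i in range(m) if rng.random() < 0.6
    }
    return cs.CellFateModel.build(states, divisions, transitions, losses)
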