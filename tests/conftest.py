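"""Shared fixtures: small peptides, toy catalogues, synthetic receptors.

Everything is generated programmatically; no data files are read.
"""

import numpy as np
import pytest

from pepscreen import (CoarseGrainedModel, ThermoState, ToyEnumerableModel,
                       make_free_peptide)


@pytest.fixture(scope="session")
def cg_model():
    return CoarseGrainedModel()


@pytest.fixture(scope="session")
def thermo():
    return ThermoState(0.60)


@pytest.fixture
def tripeptide():
    """Free A-x-A tripeptide (one variable center position)."""
    return make_free_peptide("AAA", ".x.")


@pytest.fixture
def free_peptide3():
    """Free peptide with 3 variable positions (the flattening workhorse)."""
    return make_free_peptide("KKEAAA", "...xxx")


def _random_toy(seed, nc=6, nv=2, na=5, n_bound=2, coupling=0.8):
    rng = np.random.default_rng(seed)
    bound = np.zeros(nc, dtype=bool)
    bound[:n_bound] = True
    return ToyEnumerableModel(
        e_state=rng.normal(0.0, 1.0, nc),
        bound=bound,
        u_table=rng.normal(0.0, coupling, (nc, nv, na)))


@pytest.fixture
def toy_model():
    """6 states (2 bound-like), 2 variable positions, 5-letter alphabet."""
    return _random_toy(seed=5)


@pytest.fixture
def toy_model_1pos():
    """Single variable position, full 20-letter alphabet."""
    return _random_toy(seed=9, nc=5, nv=1, na=20, n_bound=2, coupling=0.6)


@pytest.fixture
def separable_toy():
    """Toy model whose unbound subset is state-sequence separable, so the
    per-type unbound free energies f_a are known in closed form."""
    rng = np.random.default_rng(17)
    nc, nv, na = 5, 2, 6
    bound = np.array([True, True, False, False, False])
    u = np.zeros((nc, nv, na))
    # bound states: arbitrary couplings
    u[:2] = rng.normal(0.0, 1.0, (2, nv, na))
    # unbound states: identical per-type field w[a] at every position
    w = rng.normal(0.0, 0.7, na)
    for c in range(2, nc):
        for i in range(nv):
            u[c, i] = w
    model = ToyEnumerableModel(e_state=rng.normal(0.0, 0.5, nc), bound=bound,
                               u_table=u)
    model.w_field = w  # closed-form per-type unbound free energy
    return model

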