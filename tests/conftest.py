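"""Shared fixtures: small seeded ensembles and worked-example communities."""

import numpy as np
import pytest

from cctradeoff import Metacommunity, make_fixture_ensemble


@pytest.fixture(scope="session")
def two_species():
    """Worked two-species community with equilibrium (0.2, 0.4)."""
    return Metacommunity(c=[0.0625, 0.15625], m=[0.05, 0.05], h=[0.0, 0.0])


@pytest.fixture(scope="session")
def small_ensemble():
    """Ten feasible 4-species communities, fixed seed."""
    return make_fixture_ensemble(n_species=4, count=10, seed=42)


@pytest.fixture(scope="session")
def five_species_ensemble():
    """Feasible 5-species communities for scenario tests."""
    return make_fixture_ensemble(n_species=5, count=12, seed=7)


@pytest.fixture(scope="session")
def rng():
    return np.random.default_rng(2024)
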