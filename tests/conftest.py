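import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

import meadowdiv as md

settings.register_profile("ci", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def tiny_cm():
    """Two units x three species with one guild each."""
    md_df = pd.DataFrame(
        {"treatment": ["FE", "FE"], "plot": ["P1", "P1"], "transect": ["T1", "T2"]},
        index=["u1", "u2"],
    )
    return md.CommunityMatrix(
        ["u1", "u2"], ["A", "B", "C"], np.array([[3, 0, 1], [1, 2, 0]]), md_df
    )


@pytest.fixture
def tiny_guilds():
    return md.GuildTable({"A": "Ph", "B": "Pr", "C": "Ph"})


@pytest.fixture(scope="session")
def default_bundle():
    """One default synthetic study (48 x 88), shared across tests."""
    return md.simulate_community(md.SyntheticDesign(seed=11))


def random_incidence(rng, n_units=None, n_species=None):
    n_units = n_units or rng.integers(2, 9)
    n_species = n_species or rng.integers(2, 16)
    pres = (rng.random((n_units, n_species)) < rng.uniform(0.2, 0.8)).astype(int)
    units = [f"u{i}" for i in range(n_units)]
    species = [f"s{j}" for j in range(n_species)]
    return md.IncidenceMatrix(units, species, pres)
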