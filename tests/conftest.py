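import numpy as np
import pandas as pd
import pytest

from soilscape.community import CommunityTable
from soilscape.geostat import VariogramModel
from soilscape.synthetic import (
    FieldSpec,
    generate_sampling_design,
    simulate_gaussian_field,
)


@pytest.fixture(scope="session")
def study_design():
    """The 278-site layout: 248 grid sites at 215 m plus 30 infill sites."""
    return generate_sampling_design(215.0, 248, 30, seed=0)


@pytest.fixture(scope="session")
def small_design():
    return generate_sampling_design(100.0, 49, 6, seed=1)


@pytest.fixture
def matern_field():
    """Factory: one Gaussian field realization at given coordinates."""

    def make(xy, c0=0.1, c1=0.9, a=200.0, v=0.5, mean=0.0, seed=0):
        spec = FieldSpec("f", VariogramModel(c0, c1, a, v), mean=mean)
        return simulate_gaussian_field(np.asarray(xy, float), spec, seed=seed)

    return make


@pytest.fixture
def tiny_community():
    data = pd.DataFrame(
        {
            "s1": [10, 5, 0, 85],
            "s2": [40, 10, 30, 20],
            "s3": [25, 25, 25, 25],
        },
        index=["otu1", "otu2", "otu3", "otu4"],
        dtype=float,
    )
    lineages = pd.Series(
        {
            "otu1": "Bacteria;Proteobacteria;Alphaproteobacteria",
            "otu2": "Bacteria;Proteobacteria;Betaproteobacteria",
            "otu3": "Bacteria;Acidobacteria",
            "otu4": "Bacteria;Acidobacteria",
        }
    )
    return CommunityTable(data, lineages)
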