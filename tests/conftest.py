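import numpy as np
import pandas as pd
import pytest
from hypothesis import settings

from agstocks import compute_tree_stocks, load_reference_traits, plot_stocks, simulate_study

settings.register_profile("suite", derandomize=True, max_examples=50, deadline=None)
settings.load_profile("suite")


@pytest.fixture(scope="session")
def ref_traits():
    return load_reference_traits()


@pytest.fixture(scope="session")
def study():
    """One full synthetic study (250 plots, 8 classes), shared read-only."""
    return simulate_study(seed=42)


@pytest.fixture(scope="session")
def study_stocks(study):
    return compute_tree_stocks(study.census, study.plots, study.registry, study.traits)


@pytest.fixture(scope="session")
def study_plot_stocks(study, study_stocks):
    return plot_stocks(study_stocks, study.plots)


@pytest.fixture()
def toy_plots():
    return pd.DataFrame({
        "plot_id": ["P1", "P2", "P3"],
        "lulc": ["Woodland"] * 3,
        "width_m": [30.0] * 3,
        "length_m": [30.0] * 3,
    })


@pytest.fixture()
def toy_census():
    """3 species: counts 6/3/1, plot occupancy 3/2/1, DBH 10/20/30 cm."""
    rows = []
    for plot, n in zip(["P1", "P2", "P3"], [2, 2, 2]):
        rows += [("Acacia seyal", plot, 10.0)] * n
    rows += [("Ficus sp", "P1", 20.0)] * 2 + [("Ficus sp", "P2", 20.0)]
    rows += [("Parkia biglobosa", "P3", 30.0)]
    return pd.DataFrame(
        [{"plot_id": p, "species": s, "dbh_cm": d, "height_m": 8.0,
          "wood_density_g_cm3": 0.6} for s, p, d in rows]
    )
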