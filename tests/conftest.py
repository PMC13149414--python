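import numpy as np
import pytest

import ncdmap as nm


@pytest.fixture(scope="session")
def eac_graph():
    return nm.build_eac_graph()


@pytest.fixture(scope="session")
def default_sim():
    """Default-condition synthetic panel (7 x 4 x 20) with ground truth."""
    panel, truth = nm.simulate_panel(nm.SimulationConfig(seed=42))
    return panel, truth


@pytest.fixture(scope="session")
def std_panel(default_sim):
    panel, truth = default_sim
    panel_std, record = nm.standardize_covariates(panel)
    return panel_std, record, truth


@pytest.fixture(scope="session")
def full_spec(eac_graph, default_sim):
    panel, _ = default_sim
    return nm.ModelSpec(eac_graph, panel.diseases, panel.years, panel.covariates)


@pytest.fixture(scope="session")
def fitted_posterior(std_panel, full_spec):
    """One short but real fit of the full model, shared across tests."""
    panel_std, _, _ = std_panel
    cfg = nm.InferenceConfig(seed=11, iterations=700, burn_in=250, thin=3)
    return nm.sample_hyperparameters(panel_std, full_spec, cfg)


@pytest.fixture(scope="session")
def toy_panel_2x2x2():
    """Tiny 2 countries x 2 diseases x 2 years panel for exact checks."""
    graph = nm.CountryGraph(["A", "B"], [("A", "B")])
    cfg = nm.SimulationConfig(
        seed=3, n_countries=2, graph=graph, diseases=("d1", "d2"), n_years=2,
        baseline_rates={"d1": 100.0, "d2": 50.0},
    )
    panel, truth = nm.simulate_panel(cfg)
    return graph, panel, truth


def rng(seed=0):
    return np.random.default_rng(seed)
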