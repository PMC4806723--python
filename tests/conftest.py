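import pytest

from invasionphys import synthetic_data as sd


@pytest.fixture(scope="session")
def default_config():
    """Generator under the study conditions (noise on), fixed seed."""
    return sd.SimulationConfig(seed=42)


@pytest.fixture(scope="session")
def noiseless_config():
    """Every noise / random-effect parameter zeroed: closed-form expectations."""
    return sd.SimulationConfig(
        seed=0,
        conductance_noise_sd=0.0,
        mass_noise_cv=0.0,
        allocation_noise_cv=0.0,
        plot_sd=0.0,
        competition_mass_cv=0.0,
        seed_dispersion=0.0,
        exclusion_block_sd={"n_individuals": 0.0, "mean_fruits": 0.0, "mean_mass": 0.0},
        exclusion_residual_sd={"n_individuals": 0.0, "mean_fruits": 0.0, "mean_mass": 0.0},
    )


@pytest.fixture(scope="session")
def harvests(default_config):
    return sd.gen_harvests(default_config)


@pytest.fixture(scope="session")
def conductance(default_config):
    return sd.gen_conductance(default_config)


@pytest.fixture(scope="session")
def competition_pots(default_config):
    return sd.gen_competition(default_config)


@pytest.fixture(scope="session")
def exclusion_plots(default_config):
    return sd.gen_exclusion(default_config)
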