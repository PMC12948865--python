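import pytest

from rhizotrace.pipeline import analyze
from rhizotrace.simulate import SimConfig, simulate_experiment


@pytest.fixture(scope="session")
def exact_config():
    """Noise-free, contamination-free configuration: forward/inverse is exact."""
    return SimConfig(noise_sd_delta=0.0, noise_sd_mass=0.0,
                     eom_contamination_fraction=0.0, seed=11)


@pytest.fixture(scope="session")
def exact_experiment(exact_config):
    return simulate_experiment(exact_config)


@pytest.fixture(scope="session")
def exact_result(exact_config, exact_experiment):
    sim = exact_experiment
    return analyze(sim.measurements, sim.references, sim.geometry,
                   delta_eom=exact_config.delta_eom,
                   constants=exact_config.constants)


@pytest.fixture(scope="session")
def noisy_experiment():
    """Default study conditions (IRMS delta noise, mass noise, EOM)."""
    return simulate_experiment(SimConfig(seed=42))
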