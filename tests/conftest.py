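import pytest

from methap import simulate as sim


@pytest.fixture(scope="session")
def clean_x_scenario():
    """Error-free X-inactivation-like scenario (one homolog methylated)."""
    scenario = sim.make_scenario("x_inactivation", n_regions=30, error_rate=0.0, seed=5)
    reads = sim.emit_reads(scenario)
    return scenario, reads


@pytest.fixture(scope="session")
def noisy_consistent_scenario():
    """Consistent homologs at the default 1% call error rate."""
    scenario = sim.make_scenario("consistent", n_regions=30, seed=7)
    reads = sim.emit_reads(scenario)
    return scenario, reads
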