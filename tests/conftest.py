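import pytest

from bolmir.core import PipelineConfig
from bolmir.simulate import SimConfig, simulate_libraries, simulate_references


@pytest.fixture(scope="session")
def cfg():
    return PipelineConfig()


@pytest.fixture(scope="session")
def small_sim():
    """A small, fixed-seed simulated experiment shared across unit tests."""
    scfg = SimConfig(rng_seed=7, reads_per_library=3000, n_libraries=2)
    genome, bundle, truth = simulate_references(scfg)
    libraries = simulate_libraries(scfg, truth)
    return scfg, genome, bundle, truth, libraries
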