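import pytest

from mitochar import evolve_on_tree, make_reference_record
from mitochar.simulate import SimulationConfig


@pytest.fixture(scope="session")
def default_record():
    """The synthetic 16,553 bp reference mitogenome (seed 0)."""
    return make_reference_record(SimulationConfig(seed=0))


@pytest.fixture(scope="session")
def sim_tips(default_record):
    """Eight tip genomes evolved along the default guide tree."""
    return evolve_on_tree(default_record, SimulationConfig(seed=0))
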