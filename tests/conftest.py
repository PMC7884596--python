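import pytest

import hemasm as hm


@pytest.fixture(scope="session")
def scaled_truth():
    """Two species x two paralogs, reduced architecture."""
    return hm.generate_paralog_pair(hm.scaled_down_spec(seed=11))


@pytest.fixture(scope="session")
def truth_one_species():
    return hm.generate_paralog_pair(hm.scaled_down_spec(seed=11, species_divergence=0.0))


@pytest.fixture(scope="session")
def reads_err(truth_one_species):
    return hm.simulate_reads(
        truth_one_species, hm.ReadSimSpec(seed=12, coverage=50, error_rate=0.01)
    )


@pytest.fixture(scope="session")
def seed_reference(truth_one_species):
    return hm.heterologous_reference(truth_one_species, 0.125, seed=13)


@pytest.fixture(scope="session")
def assembled_state(reads_err, seed_reference):
    return hm.assemble(reads_err, seed_reference)
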