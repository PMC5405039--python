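import pytest
from hypothesis import settings

import q9pbm
from q9pbm.simulate import DEFAULT_MOTIFS, expected_signals

settings.register_profile("ci", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def full_design():
    """The complete 9-mer slide (seed 0), shared across the session."""
    return q9pbm.design_array(0)


@pytest.fixture(scope="session")
def full_expected(full_design):
    """Noise-free expected intensities of the three-motif hybridisation."""
    return expected_signals(full_design, list(DEFAULT_MOTIFS), 500.0)


@pytest.fixture(scope="session")
def toy_design():
    """Tiny 3-mer universe (32 canonical k-mers) for exhaustive oracles."""
    return q9pbm.design_array(0, k=3, n_replicates=8, n_random=4,
                              n_manufacturer=2)
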