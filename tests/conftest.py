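import numpy as np
import pytest

from sre_selscan import simulate


@pytest.fixture(scope="session")
def fix():
    """One synthetic study under the default conditions."""
    return simulate.simulate_fixture(simulate.SimulationConfig(seed=42))


@pytest.fixture(scope="session")
def fixture_dir(fix, tmp_path_factory):
    """The same study written to disk as VCF/GFF3/FASTA/TSV/BED."""
    out = tmp_path_factory.mktemp("fixture")
    paths = simulate.write_fixture(fix, out)
    return paths


@pytest.fixture()
def rng():
    return np.random.default_rng(0)
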