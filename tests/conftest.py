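import pytest

from contigvar import SimConfig, simulate_assembly


@pytest.fixture(scope="session")
def small_sim():
    """A small seeded synthetic assembly shared across tests."""
    return simulate_assembly(SimConfig(seed=7, n_contigs=8))


@pytest.fixture(scope="session")
def small_fixture_dir(small_sim, tmp_path_factory):
    """The same assembly written out as ACE/QUAL/MID/assignment files."""
    outdir = tmp_path_factory.mktemp("fixture")
    paths = small_sim.write(outdir)
    return paths
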