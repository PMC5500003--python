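import pytest

from taurna import chargecalc, constructs


@pytest.fixture(scope="session")
def dtau187():
    return constructs.delta_tau187()


@pytest.fixture(scope="session")
def generic_rna():
    return chargecalc.RNASpec(name="RNA")


@pytest.fixture(scope="session")
def trna_25kda():
    return chargecalc.RNASpec(name="tRNA", chain_mass=25000.0)
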