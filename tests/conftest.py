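import pytest

import cenrich as cr


@pytest.fixture(scope="session")
def panel():
    """The six shipped enzymes, by name."""
    return {e.name: e for e in cr.default_panel()}


@pytest.fixture(scope="session")
def sne(panel):
    """The three-enzyme high-frequency cutter combination ScrFI+NlaIV+EcoO109I."""
    return (panel["ScrFI"], panel["NlaIV"], panel["EcoO109I"])


@pytest.fixture(scope="session")
def sne_plan(sne):
    return cr.DigestionPlan(sne)


@pytest.fixture(scope="session")
def toy_genome(sne):
    """Synthetic genome with one site-free 34.2-kb array, target fraction 0.10."""
    spec = cr.SyntheticGenomeSpec(forbidden_enzymes=sne, seed=11)
    return cr.make_toy_genome(spec)
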