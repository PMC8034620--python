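import pytest

from spacerseq.models import BarcodeSpec
from spacerseq.simulate import (
    default_cassette,
    default_parent_model,
    design_prespacer,
    make_phage_genome,
)


@pytest.fixture(scope="session")
def genome():
    return make_phage_genome(20000, gc=0.4, seed=101)


@pytest.fixture(scope="session")
def parent_model():
    """Single-repeat parent array (no pre-existing spacers)."""
    return default_parent_model(seed=202)


@pytest.fixture(scope="session")
def parent_model_3sp():
    """Parent array with three original spacers (recombination scenarios)."""
    return default_parent_model(seed=202, n_spacers=3)


@pytest.fixture(scope="session")
def barcodes():
    return [BarcodeSpec("S1", "ACG"), BarcodeSpec("S2", "TGCA"),
            BarcodeSpec("S3", "GATTC")]


@pytest.fixture(scope="session")
def substrate():
    """45-bp duplex, 8-nt 3' overhangs, central BbsI cassette."""
    return design_prespacer(45, 8, 8, with_bbsi=True, seed=303)


@pytest.fixture(scope="session")
def cassette():
    return default_cassette()
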