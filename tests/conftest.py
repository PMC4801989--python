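import random

import pytest

from pepkit import default_databases, parse_peptide

# Example assignment target: a thioester-capped nonamer whose single-Ser
# deletion and double R/S deletion + sodiation land on the reference masses
# used by the acceptance tests.
EXAMPLE_SEQUENCE = "SYFPKFPKR"
EXAMPLE_NTERM = "unmodified"
EXAMPLE_CTERM = "ethyl 3-mercaptopropionate thioester"


@pytest.fixture(scope="session")
def db():
    return default_databases()


@pytest.fixture(scope="session")
def example_seq(db):
    return parse_peptide(EXAMPLE_SEQUENCE, EXAMPLE_NTERM, EXAMPLE_CTERM, db=db)


@pytest.fixture
def rng():
    return random.Random(20160224)


@pytest.fixture(scope="session")
def rdkit_masses():
    """Independent element-mass source for cross-checking our table."""
    from rdkit import Chem

    pt = Chem.GetPeriodicTable()
    return lambda symbol: pt.GetMostCommonIsotopeMass(symbol)
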