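import numpy as np
import pytest

from contactsieve.geometry import build_torsion_chain, segments_from_ss, to_coordinates
from contactsieve.synthetic import gsgs_fixture, make_toy_sheet


@pytest.fixture(scope="session")
def toy_sheet():
    """Default 3-strand, 19-residue antiparallel sheet fixture."""
    return make_toy_sheet(3, 5, 2)


@pytest.fixture(scope="session")
def gsgs():
    """Toy sheet plus the five-contact design (one erroneous)."""
    return gsgs_fixture()


@pytest.fixture()
def extended_chain():
    return build_torsion_chain("ADKLMNPQRS", [])


@pytest.fixture()
def hairpin_chain():
    ss = "CCEEEECCEEEECC"
    return build_torsion_chain("A" * len(ss), segments_from_ss(ss))
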