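import numpy as np
import pytest

from hexitope import synthetic_data as synth
from hexitope.contact_analysis import ContactTable


@pytest.fixture(scope="session")
def toy_complex():
    """Default hexamer + 2 antibodies with the reference contact map."""
    return synth.build_toy_complex()


@pytest.fixture(scope="session")
def bundled():
    return synth.bundled_tables()


@pytest.fixture(scope="session")
def channel_table(bundled) -> ContactTable:
    """The bundled hemichannel-residue probabilities as a ContactTable."""
    return ContactTable.from_residue_frame(bundled["channel_contacts"], partner="AB")


@pytest.fixture(scope="session")
def family_fasta(tmp_path_factory):
    path = tmp_path_factory.mktemp("family") / "family.fasta"
    ref_seq = synth.write_family_fasta(str(path))
    return str(path), ref_seq


def brute_force_min_distance(coords_a, coords_b) -> float:
    """O(n*m) all-pairs minimum distance, independent of the library path."""
    best = np.inf
    for a in np.atleast_2d(coords_a):
        for b in np.atleast_2d(coords_b):
            d = float(np.sqrt(((a - b) ** 2).sum()))
            best = min(best, d)
    return best
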