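import numpy as np
import pytest

from condock.structure import Residue, Structure
from condock.synthetic import ToyComplexSpec, make_toy_complex


def single_atom_structure(element="C", coord=(0.0, 0.0, 0.0), name="CA"):
    return Structure(
        "single",
        [Residue("A", 1, "", "ALA", [name], [element], np.array([coord]))],
    )


def blob_structure(centers, chain="A", resname="ALA"):
    """One single-carbon-atom residue per center."""
    residues = [
        Residue(chain, i + 1, "", resname, ["CA"], ["C"], np.array([c], dtype=float))
        for i, c in enumerate(centers)
    ]
    return Structure(f"blob_{chain}", residues)


@pytest.fixture(scope="session")
def toy_complex():
    return make_toy_complex(ToyComplexSpec(seed=1))


@pytest.fixture(scope="session")
def toy_complex_small():
    return make_toy_complex(
        ToyComplexSpec(n_residues_a=12, n_residues_b=10, n_contacts=3, seed=3)
    )
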