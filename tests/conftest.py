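import numpy as np
import pytest

from crossepi.structio import Atom, Residue, Structure, assign_radii
from crossepi.synthetic import ToyFamilySpec, make_analysis_bundle, make_ideal_helix, make_toy_family


@pytest.fixture(scope="session")
def helix():
    """Radius-assigned 12-residue mixed-sequence ideal helix."""
    return assign_radii(make_ideal_helix("ADKLQESNVRGT"))


@pytest.fixture(scope="session")
def toy_family():
    """6-member family with 4 planted exclusive substitutions + 1 insertion."""
    planted = {2, 7, 15, 18, 30}
    spec = ToyFamilySpec(
        n_members=6,
        length=60,
        seed=11,
        conserved_columns=tuple(c for c in range(46) if c not in planted),
        conservative_columns=(48, 50),
        exclusive_substitutions=((2, "N", "K"), (7, "V", "G"), (15, "Q", "K"), (18, "V", "M")),
        insertion=(30, "S"),
    )
    return make_toy_family(spec)


@pytest.fixture(scope="session")
def bundle(tmp_path_factory):
    """Full synthetic analysis bundle (alignment, structures, patches, config)."""
    out = tmp_path_factory.mktemp("bundle")
    truth = make_analysis_bundle(out, seed=7)
    return truth


def single_atom_structure(radius: float = 1.6, element: str = "C") -> Structure:
    atom = Atom(1, "CA", element, np.zeros(3), vdw_radius=radius)
    return Structure("one", {"A": [Residue("A", 1, "GLY", [atom])]})


def cluster_structure(centers, radius: float = 1.7) -> Structure:
    """One residue per center, single carbon atom each, common radius."""
    residues = [
        Residue("A", i + 1, "GLY", [Atom(i + 1, "CA", "C", np.asarray(c, float), vdw_radius=radius)])
        for i, c in enumerate(centers)
    ]
    return Structure("cluster", {"A": residues})
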