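import numpy as np
import pytest

from coassembly.topology import Kind, build_composition
from coassembly.trajectory import Frame


@pytest.fixture(scope="session")
def templates():
    from coassembly.synthetic import default_templates

    return default_templates()


@pytest.fixture
def reference_epi():
    """48 peptides, 12 drugs (+1), 48 Zn2+ in an 83 A box -> 96 NO3-, 12 Cl-."""
    return build_composition(48, 12, 1, 48, 83.0)


def single_atom_frame(positions, box=100.0, kinds=None, radii=None, groups=None):
    """Frame of single-atom components at given positions (test helper)."""
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    kinds = kinds or [Kind.ZN] * n
    return Frame(
        coords=positions,
        box_length=box,
        atom_component=np.arange(n),
        component_kind=list(kinds),
        atom_group=list(groups or ["ion"] * n),
        atom_radius=np.asarray(radii if radii is not None else [1.5] * n, dtype=float),
    )


@pytest.fixture
def make_frame():
    return single_atom_frame


def random_component_frame(rng, n_components=300, box=60.0, atoms_per_component=2):
    """Random multi-atom components, used against the brute-force detector."""
    kinds = [
        (Kind.PEPTIDE, Kind.DRUG, Kind.ZN, Kind.NO3)[rng.integers(4)]
        for _ in range(n_components)
    ]
    coords, atom_component = [], []
    for ci in range(n_components):
        center = rng.uniform(0, box, 3)
        for _ in range(atoms_per_component):
            coords.append(center + rng.normal(scale=1.0, size=3))
            atom_component.append(ci)
    n_atoms = len(coords)
    return Frame(
        coords=np.array(coords),
        box_length=box,
        atom_component=np.array(atom_component),
        component_kind=kinds,
        atom_group=["g"] * n_atoms,
        atom_radius=np.full(n_atoms, 1.5),
    )
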