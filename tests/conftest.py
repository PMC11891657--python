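import numpy as np
import pytest

from dockem.evaluate import generate_fixture
from dockem.structio import (
    Atom,
    Bond,
    ForceFieldTable,
    Ligand,
    assign_parameters,
    detect_rotatable_bonds,
    ligand_diameter,
)


def make_ligand(spec, bonds, charges=None, name="LIG"):
    """Build a ligand from [(element, (x, y, z)), ...] and bond triples."""
    atoms = []
    for i, (elem, xyz) in enumerate(spec, start=1):
        q = charges[i - 1] if charges else 0.0
        atoms.append(Atom(index=i, name=f"{elem}{i}", element=elem,
                          coords=np.asarray(xyz, float), charge=q))
    bond_objs = [Bond(a, b, str(o)) for a, b, o in bonds]
    return Ligand(atoms, bond_objs, name=name)


@pytest.fixture
def butane():
    """Four-carbon chain: exactly one rotatable (central) bond."""
    lig = make_ligand(
        [("C", (0.0, 0.0, 0.0)), ("C", (1.53, 0.0, 0.0)),
         ("C", (2.2, 1.35, 0.0)), ("C", (3.73, 1.35, 0.0))],
        [(1, 2, 1), (2, 3, 1), (3, 4, 1)],
    )
    assign_parameters(lig)
    detect_rotatable_bonds(lig)
    ligand_diameter(lig)
    return lig


@pytest.fixture
def benzene():
    """Aromatic six-ring: no rotatable bonds, 12-fold graph symmetry."""
    r = 1.40 / (2 * np.sin(np.pi / 6))
    spec = [("C", (r * np.cos(2 * np.pi * i / 6), r * np.sin(2 * np.pi * i / 6), 0.0))
            for i in range(6)]
    bonds = [(i + 1, (i + 1) % 6 + 1, "ar") for i in range(6)]
    lig = make_ligand(spec, bonds, name="BNZ")
    assign_parameters(lig)
    detect_rotatable_bonds(lig)
    ligand_diameter(lig)
    return lig


@pytest.fixture
def biphenyl():
    """Two six-rings joined by one single bond: exactly one rotatable bond."""
    r = 1.40 / (2 * np.sin(np.pi / 6))
    spec = []
    for cx in (0.0, 2 * r + 1.48):
        for i in range(6):
            ang = 2 * np.pi * i / 6
            spec.append(("C", (cx + r * np.cos(ang), r * np.sin(ang), 0.0)))
    bonds = [(i + 1, (i + 1) % 6 + 1, "ar") for i in range(6)]
    bonds += [(6 + i + 1, 6 + (i + 1) % 6 + 1, "ar") for i in range(6)]
    bonds += [(1, 10, 1)]  # inter-ring single bond (atom 1 faces atom 10)
    lig = make_ligand(spec, bonds, name="BIP")
    assign_parameters(lig)
    detect_rotatable_bonds(lig)
    ligand_diameter(lig)
    return lig


@pytest.fixture(scope="session")
def toy_fixture():
    """The standard synthetic docking problem (R = 3 A, 1 A spacing)."""
    return generate_fixture(seed=11)


@pytest.fixture
def ff_table():
    return ForceFieldTable.amber99()


@pytest.fixture(scope="session")
def selfdock_results():
    """Memoized self-docking recovery batches, keyed by map resolution."""
    from dockem.benchmarks import selfdock_trial

    cache = {}

    def get(resolution):
        if resolution not in cache:
            cache[resolution] = [selfdock_trial(seed, resolution)
                                 for seed in range(10)]
        return cache[resolution]

    return get
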