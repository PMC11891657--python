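"""Small shared builders used across test modules."""

import numpy as np

from dockem.structio import Atom, Bond, Ligand, assign_parameters


def ethane_like():
    """Two heavy atoms only: both fragments are single atoms, nothing rotates."""
    return Ligand(
        [Atom(index=1, name="C1", element="C", coords=(0, 0, 0)),
         Atom(index=2, name="C2", element="C", coords=(1.53, 0, 0))],
        [Bond(1, 2, "1")],
    )


def collinear_three():
    return Ligand(
        [Atom(index=1, name="C1", element="C", coords=(0, 0, 0)),
         Atom(index=2, name="C2", element="C", coords=(2, 0, 0)),
         Atom(index=3, name="C3", element="C", coords=(5, 0, 0))],
        [Bond(1, 2, "1"), Bond(2, 3, "1")],
    )


def random_parameterized_ligand(seed, n=10):
    """Chain ligand with random coordinates and assigned parameters."""
    rng = np.random.default_rng(seed)
    elements = rng.choice(["C", "N", "O", "S"], size=n)
    xyz = rng.uniform(-4, 4, size=(n, 3))
    atoms = [Atom(index=i + 1, name=f"{elements[i]}{i+1}", element=str(elements[i]),
                  coords=xyz[i], charge=float(rng.uniform(-0.5, 0.5)))
             for i in range(n)]
    bonds = [Bond(i + 1, i + 2, "1") for i in range(n - 1)]
    lig = Ligand(atoms, bonds)
    assign_parameters(lig)
    return lig
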