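"""Molecular structure I/O, force-field parameterization, and ligand topology.

Ligands are read from Tripos MOL2 (atoms must carry partial charges; the
BOND table is mandatory because it defines the rotatable-bond degrees of
freedom). Receptors are read from PDB. Coordinates are Cartesian angstroms
in the map frame throughout.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
from scipy.spatial.distance import pdist

from .errors import (
    GeometryError,
    ParameterError,
    ParseError,
    TopologyError,
    ValidationError,
)

__all__ = [
    "Atom",
    "Bond",
    "Ligand",
    "Protein",
    "Residue",
    "ForceFieldTable",
    "read_mol2",
    "write_mol2",
    "read_pdb",
    "write_pdb",
    "assign_parameters",
    "detect_rotatable_bonds",
    "ligand_diameter",
]


@dataclass
class Atom:
    """One atom with force-field parameters.

    ``mass`` (u), ``charge`` (elementary charges), ``vdw_radius`` (A, the
    Lennard-Jones minimum-distance radius r so that a pair minimizes at
    r_i + r_j), ``well_depth`` (kcal/mol). Parameters other than the charge
    are filled in by :func:`assign_parameters`.
    """

    index: int  # 1-based, as in the source file
    name: str
    element: str
    coords: np.ndarray
    charge: float = 0.0
    mass: float | None = None
    vdw_radius: float | None = None
    well_depth: float | None = None
    atom_type: str = ""  # SYBYL type for MOL2 atoms

    def __post_init__(self) -> None:
        self.coords = np.asarray(self.coords, dtype=float)
        if self.coords.shape != (3,) or not np.all(np.isfinite(self.coords)):
            raise ValidationError(f"atom {self.index}: non-finite or malformed coordinates")


@dataclass(frozen=True)
class Bond:
    """A bond between two 1-based atom indices with a MOL2 order token."""

    atom1: int
    atom2: int
    order: str = "1"

    def __post_init__(self) -> None:
        if self.atom1 == self.atom2:
            raise ValidationError(f"bond joins atom {self.atom1} to itself")
        object.__setattr__(self, "order", str(self.order).lower())


class _Molecule:
    """Shared coordinate-array plumbing for Ligand and Protein."""

    atoms: list[Atom]

    @property
    def coords(self) -> np.ndarray:
        return np.array([a.coords for a in self.atoms], dtype=float)

    def set_coords(self, coords: np.ndarray) -> None:
        coords = np.asarray(coords, dtype=float)
        if coords.shape != (len(self.atoms), 3):
            raise ValidationError("coordinate array shape mismatch")
        for atom, xyz in zip(self.atoms, coords):
            atom.coords = xyz

    @property
    def masses(self) -> np.ndarray:
        return np.array([_require(a.mass, a, "mass") for a in self.atoms])

    @property
    def charges(self) -> np.ndarray:
        return np.array([a.charge for a in self.atoms])

    @property
    def vdw_radii(self) -> np.ndarray:
        return np.array([_require(a.vdw_radius, a, "vdw_radius") for a in self.atoms])

    @property
    def well_depths(self) -> np.ndarray:
        return np.array([_require(a.well_depth, a, "well_depth") for a in self.atoms])

    @property
    def elements(self) -> list[str]:
        return [a.element for a in self.atoms]


def _require(value: float | None, atom: Atom, what: str) -> float:
    if value is None:
        raise ParameterError(
            f"atom {atom.index} ({atom.name}) has no {what}; run assign_parameters first"
        )
    return value


class Ligand(_Molecule):
    """A small molecule: atoms, bonds, and derived torsional topology.

    ``diameter`` is the maximum inter-atomic distance and ``c_lim`` is half
    of it — the radius of the center-distance restraint keeping the pose
    near the local-map center. Both are filled by :func:`ligand_diameter`.
    """

    def __init__(self, atoms: list[Atom], bonds: list[Bond], name: str = "LIG"):
        self.atoms = list(atoms)
        self.bonds = list(bonds)
        self.name = name
        self.rotatable_bonds: list[Bond] = []
        self.diameter: float | None = None
        self.c_lim: float | None = None
        self._validate()

    def _validate(self) -> None:
        n = len(self.atoms)
        indices = {a.index for a in self.atoms}
        if len(indices) != n:
            raise ValidationError("duplicate atom indices")
        for b in self.bonds:
            if b.atom1 not in indices or b.atom2 not in indices:
                raise ValidationError(f"bond {b.atom1}-{b.atom2} references a missing atom")
        if n > 1 and not nx.is_connected(self.bond_graph()):
            raise ValidationError("ligand bond graph is disconnected")

    def bond_graph(self) -> nx.Graph:
        g = nx.Graph()
        for a in self.atoms:
            g.add_node(a.index, element=a.element)
        for b in self.bonds:
            g.add_edge(b.atom1, b.atom2, order=b.order)
        return g

    def index_of(self, atom_index: int) -> int:
        """Map a 1-based atom index to the position in ``self.atoms``."""
        for pos, a in enumerate(self.atoms):
            if a.index == atom_index:
                return pos
        raise KeyError(atom_index)

    def with_coords(self, coords: np.ndarray) -> "Ligand":
        out = copy.deepcopy(self)
        out.set_coords(coords)
        return out


@dataclass
class Residue:
    chain: str
    resid: int
    icode: str
    resname: str
    atom_positions: list[int] = field(default_factory=list)  # positions in Protein.atoms


class Protein(_Molecule):
    """A receptor: atoms grouped into residues."""

    def __init__(self, atoms: list[Atom], residues: list[Residue]):
        self.atoms = list(atoms)
        self.residues = list(residues)
        claimed = [p for r in residues for p in r.atom_positions]
        if sorted(claimed) != list(range(len(self.atoms))):
            raise ValidationError("every atom must belong to exactly one residue")

    def with_coords(self, coords: np.ndarray) -> "Protein":
        out = copy.deepcopy(self)
        out.set_coords(coords)
        return out


# --- force field ---------------------------------------------------------

#: per-element Lennard-Jones parameters in the AMBER99 convention
#: (vdw_radius = Rmin/2 in A, well depth in kcal/mol), atomic masses in u,
#: and a crude per-element default partial charge used for receptor atoms
#: when no per-atom charges are supplied.
_AMBER99_ELEMENTS: dict[str, tuple[float, float, float, float]] = {
    # element: (vdw_radius, well_depth, mass, default_charge)
    "H": (1.2000, 0.0157, 1.008, 0.10),
    "C": (1.9080, 0.0860, 12.011, 0.05),
    "N": (1.8240, 0.1700, 14.007, -0.40),
    "O": (1.6612, 0.2100, 15.999, -0.45),
    "S": (2.0000, 0.2500, 32.060, -0.15),
    "P": (2.1000, 0.2000, 30.974, 0.40),
    "F": (1.7500, 0.0610, 18.998, -0.15),
    "CL": (1.9480, 0.2650, 35.450, -0.10),
    "BR": (2.2200, 0.3200, 79.904, -0.10),
    "I": (2.3500, 0.4000, 126.904, -0.05),
}


class ForceFieldTable:
    """Per-element vdW radius, well depth, mass, and default charge.

    The lookup is total over the supported element alphabet; unknown
    elements raise :class:`ParameterError`.
    """

    def __init__(self, entries: dict[str, tuple[float, float, float, float]]):
        self.entries = {k.upper(): v for k, v in entries.items()}

    @classmethod
    def amber99(cls) -> "ForceFieldTable":
        return cls(_AMBER99_ELEMENTS)

    def __contains__(self, element: str) -> bool:
        return element.upper() in self.entries

    def lookup(self, element: str) -> tuple[float, float, float, float]:
        key = element.upper()
        if key not in self.entries:
            raise ParameterError(f"no force-field entry for element {element!r}")
        return self.entries[key]


def assign_parameters(
    mol: Ligand | Protein,
    table: ForceFieldTable | None = None,
    *,
    charge_overrides: dict[int, float] | None = None,
):
    """Fill in mass, vdW radius, and well depth for every atom, in place.

    Ligand charges (from the MOL2) are never touched; protein atoms get the
    table's per-element default charge unless ``charge_overrides`` (keyed by
    1-based atom index) supplies a value. Returns ``mol`` for chaining.
    """
    table = table or ForceFieldTable.amber99()
    unknown = [a for a in mol.atoms if a.element not in table]
    if unknown:
        names = ", ".join(f"{a.index}:{a.element}" for a in unknown[:10])
        raise ParameterError(f"unknown atom types for atoms: {names}")
    is_protein = isinstance(mol, Protein)
    for a in mol.atoms:
        r, eps, mass, q_default = table.lookup(a.element)
        a.vdw_radius, a.well_depth, a.mass = r, eps, mass
        if is_protein:
            if charge_overrides and a.index in charge_overrides:
                a.charge = charge_overrides[a.index]
            else:
                a.charge = q_default
    return mol


# --- MOL2 ----------------------------------------------------------------

_MOL2_ELEMENT_FIX = {"CL": "Cl", "BR": "Br"}


def _element_from_sybyl(atom_type: str, name: str) -> str:
    base = atom_type.split(".")[0] if atom_type else ""
    if base and base.upper() in _AMBER99_ELEMENTS:
        return base.capitalize() if len(base) > 1 else base.upper()
    # fall back to the leading letters of the atom name
    letters = "".join(c for c in name if c.isalpha())
    for k in (2, 1):
        if letters[:k].upper() in _AMBER99_ELEMENTS:
            return letters[:k].capitalize() if k > 1 else letters[:k].upper()
    return base or letters[:1].upper()


def read_mol2(text: str) -> Ligand:
    """Parse a Tripos MOL2 document into a :class:`Ligand`.

    Only the MOLECULE/ATOM/BOND sections are interpreted; every atom row
    must carry a partial charge, and a BOND section is mandatory.
    """
    sections: dict[str, list[str]] = {}
    current: list[str] | None = None
    mol_name = "LIG"
    for raw in text.splitlines():
        line = raw.rstrip()
        if line.startswith("@<TRIPOS>"):
            key = line[len("@<TRIPOS>"):].strip().upper()
            current = sections.setdefault(key, [])
            continue
        if current is not None and line.strip() and not line.startswith("#"):
            current.append(line)
    if "ATOM" not in sections or not sections["ATOM"]:
        raise ParseError("MOL2 document has no @<TRIPOS>ATOM section")
    if "BOND" not in sections or not sections["BOND"]:
        raise TopologyError("MOL2 document has no @<TRIPOS>BOND table")
    if sections.get("MOLECULE"):
        mol_name = sections["MOLECULE"][0].strip() or "LIG"

    atoms: list[Atom] = []
    for row in sections["ATOM"]:
        parts = row.split()
        if len(parts) < 9:
            raise ParseError(f"MOL2 atom row lacks a charge column: {row!r}")
        try:
            idx = int(parts[0])
            xyz = np.array([float(parts[2]), float(parts[3]), float(parts[4])])
        except ValueError as exc:
            raise ParseError(f"malformed MOL2 atom row: {row!r}") from exc
        try:
            charge = float(parts[8])
        except ValueError as exc:
            raise ParseError(f"non-numeric charge in MOL2 atom row: {row!r}") from exc
        atype = parts[5]
        atoms.append(
            Atom(
                index=idx,
                name=parts[1],
                element=_element_from_sybyl(atype, parts[1]),
                coords=xyz,
                charge=charge,
                atom_type=atype,
            )
        )

    bonds: list[Bond] = []
    for row in sections["BOND"]:
        parts = row.split()
        if len(parts) < 4:
            raise ParseError(f"malformed MOL2 bond row: {row!r}")
        try:
            a1, a2 = int(parts[1]), int(parts[2])
        except ValueError as exc:
            raise ParseError(f"malformed MOL2 bond row: {row!r}") from exc
        bonds.append(Bond(a1, a2, parts[3]))

    return Ligand(atoms, bonds, name=mol_name)


def write_mol2(lig: Ligand) -> str:
    lines = ["@<TRIPOS>MOLECULE", lig.name, f"{len(lig.atoms)} {len(lig.bonds)} 0 0 0",
             "SMALL", "USER_CHARGES", "", "@<TRIPOS>ATOM"]
    for a in lig.atoms:
        atype = a.atom_type or a.element
        lines.append(
            f"{a.index:>7d} {a.name:<8s} {a.coords[0]:>10.4f} {a.coords[1]:>10.4f} "
            f"{a.coords[2]:>10.4f} {atype:<8s} 1 {lig.name:<8s} {a.charge:>10.6f}"
        )
    lines.append("@<TRIPOS>BOND")
    for i, b in enumerate(lig.bonds, start=1):
        lines.append(f"{i:>6d} {b.atom1:>5d} {b.atom2:>5d} {b.order:>4s}")
    return "\n".join(lines) + "\n"


# --- PDB -----------------------------------------------------------------

def read_pdb(text: str) -> Protein:
    """Parse ATOM/HETATM records from a PDB document (fixed columns)."""
    atoms: list[Atom] = []
    residues: dict[tuple[str, int, str], Residue] = {}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.startswith(("ATOM  ", "HETATM")):
            continue
        try:
            serial = int(line[6:11])
            name = line[12:16].strip()
            resname = line[17:20].strip()
            chain = line[21:22].strip() or "A"
            resid = int(line[22:26])
            icode = line[26:27].strip()
            x = float(line[30:38])
            y = float(line[38:46])
            z = float(line[46:54])
        except (ValueError, IndexError) as exc:
            raise ParseError(f"malformed PDB record at line {lineno}: {line!r}") from exc
        element = line[76:78].strip() if len(line) >= 78 else ""
        if not element:
            stripped = line[12:16].strip("0123456789 ")
            element = stripped[:2].capitalize() if stripped[:2].upper() in _AMBER99_ELEMENTS \
                else stripped[:1].upper()
        else:
            element = element.capitalize() if len(element) > 1 else element.upper()
        pos = len(atoms)
        atoms.append(Atom(index=serial, name=name, element=element, coords=(x, y, z)))
        key = (chain, resid, icode)
        if key not in residues:
            residues[key] = Residue(chain, resid, icode, resname)
        residues[key].atom_positions.append(pos)
    if not atoms:
        raise ValidationError("PDB document contains no ATOM/HETATM records")
    return Protein(atoms, list(residues.values()))


def write_pdb(prot: Protein) -> str:
    lines = []
    for res in prot.residues:
        for pos in res.atom_positions:
            a = prot.atoms[pos]
            name = a.name if len(a.name) == 4 else f" {a.name:<3s}"
            lines.append(
                f"ATOM  {a.index:>5d} {name:<4s}{'':1s}{res.resname:>3s} {res.chain:1s}"
                f"{res.resid:>4d}{res.icode:1s}   {a.coords[0]:>8.3f}{a.coords[1]:>8.3f}"
                f"{a.coords[2]:>8.3f}{1.0:>6.2f}{0.0:>6.2f}          {a.element:>2s}"
            )
    lines.append("END")
    return "\n".join(lines) + "\n"


# --- topology ------------------------------------------------------------

def detect_rotatable_bonds(lig: Ligand, *, include_amide: bool = False) -> list[Bond]:
    """Find freely rotatable bonds from the MOL2 bond table.

    A bond is rotatable when it is a single bond ("1" order token; amide
    "am" bonds optionally included), lies in no ring, and its removal
    splits the molecule into two fragments of at least two atoms each
    (rotating a terminal atom about its own bond moves nothing).
    The result is stored on ``lig.rotatable_bonds`` and returned.
    """
    g = lig.bond_graph()
    bridges = set(frozenset(e) for e in nx.bridges(g)) if g.number_of_edges() else set()
    allowed = {"1"} | ({"am"} if include_amide else set())
    rotatable = []
    for b in lig.bonds:
        if b.order not in allowed:
            continue
        if frozenset((b.atom1, b.atom2)) not in bridges:
            continue  # in a ring
        h = g.copy()
        h.remove_edge(b.atom1, b.atom2)
        comp = nx.node_connected_component(h, b.atom1)
        n1 = len(comp)
        n2 = g.number_of_nodes() - n1
        if n1 >= 2 and n2 >= 2:
            rotatable.append(b)
    lig.rotatable_bonds = rotatable
    return rotatable


def ligand_diameter(lig: Ligand) -> float:
    """Maximum inter-atomic distance (A); also sets ``lig.c_lim`` = half of it."""
    if len(lig.atoms) < 2:
        raise GeometryError("ligand diameter undefined for fewer than two atoms")
    d = float(pdist(lig.coords).max())
    if not math.isfinite(d) or d <= 0:
        raise GeometryError("degenerate ligand geometry: all atoms coincide")
    lig.diameter = d
    lig.c_lim = d / 2.0
    return d
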