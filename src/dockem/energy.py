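"""The composite docking energy and its four terms.

    E_total = w1*E_CC + w2*E_intra + w3*E_inter + w4*E_dis

* E_CC = 1 - CC(pose, local map): the map-fit term.
* E_intra: protein-ligand Lennard-Jones + Coulomb over a preselected
  interface subset of protein atoms (those within half the ligand diameter
  of the local-map cube).
* E_inter: intra-ligand Lennard-Jones over nonbonded pairs (1-2 and 1-3
  pairs excluded by default; see ``literal_pairs``).
* E_dis: a flat-bottom restraint on the pose centroid, zero within c_lim
  of the local-map center and equal to the center distance beyond it.

Lennard-Jones pairs use A = eps R^12, B = 2 eps R^6 with R = r_i + r_j and
eps = sqrt(eps_i eps_j), so a pair at its minimum distance contributes
exactly -eps. The Coulomb term is q_i q_j / (4 d) in arbitrary units with
all physical constants absorbed into w22. Distances are clamped below at
0.3 A so clashed poses stay finite and ordered rather than overflowing.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import networkx as nx
import numpy as np
from scipy.spatial.distance import cdist

from .density import LocalMap, kernel_width, ligand_region_cc
from .errors import ParameterError
from .structio import Ligand, Protein

__all__ = [
    "EnergyWeights",
    "EnergyBreakdown",
    "EnergyModel",
    "select_interface_atoms",
    "e_intra",
    "e_inter",
    "e_dis",
    "e_total",
    "CLASH_DISTANCE",
]

#: lower clamp on inter-atomic distances (A) in the LJ/Coulomb terms
CLASH_DISTANCE = 0.3


@dataclass(frozen=True)
class EnergyWeights:
    """Weights of the composite energy; all dimensionless.

    Defaults put the bounded map term (E_CC in [0, 2]) and the clamped
    physics terms on comparable scales for typical drug-like ligands; they
    are configuration, not calibrated constants. ``K`` scales both the
    local Metropolis temperature and the replica-swap criterion.
    """

    w1: float = 10.0
    w2: float = 0.1
    w3: float = 0.1
    w4: float = 1.0
    w21: float = 1.0
    w22: float = 1.0
    K: float = 1.0

    def __post_init__(self) -> None:
        vals = (self.w1, self.w2, self.w3, self.w4, self.w21, self.w22, self.K)
        if not all(math.isfinite(v) for v in vals):
            raise ParameterError("energy weights must be finite")
        if min(self.w1, self.w2, self.w3, self.w4) < 0:
            raise ParameterError("term weights w1..w4 must be non-negative")
        if self.K <= 0:
            raise ParameterError("swap constant K must be positive")


@dataclass(frozen=True)
class EnergyBreakdown:
    """Per-term energy values for one pose; ``total`` is their weighted sum."""

    e_cc: float
    e_intra: float
    e_inter: float
    e_dis: float
    total: float
    cc: float

    def as_dict(self) -> dict:
        return {
            "E_CC": self.e_cc,
            "E_intra": self.e_intra,
            "E_inter": self.e_inter,
            "E_dis": self.e_dis,
            "E_total": self.total,
            "CC": self.cc,
        }


# --- interface selection -------------------------------------------------

def select_interface_atoms(prot: Protein, local: LocalMap, lig: Ligand) -> np.ndarray:
    """Positions of protein atoms near the local-map cube.

    An atom is selected when its distance to the cube (zero inside) is
    strictly less than half the ligand diameter.
    """
    from .structio import ligand_diameter

    if lig.c_lim is None:
        ligand_diameter(lig)
    lo, hi = local.cube_bounds()
    coords = prot.coords
    clamped = np.clip(coords, lo, hi)
    dist = np.linalg.norm(coords - clamped, axis=1)
    return np.flatnonzero(dist < lig.c_lim)


# --- pairwise terms ------------------------------------------------------

def _lj_ab(r_i, eps_i, r_j, eps_j):
    """A/B Lennard-Jones coefficient matrices for two parameter sets."""
    R = np.add.outer(np.asarray(r_i, float), np.asarray(r_j, float))
    eps = np.sqrt(np.outer(eps_i, eps_j))
    R6 = R ** 6
    return eps * R6 * R6, 2.0 * eps * R6


def e_intra(
    prot: Protein,
    subset: np.ndarray,
    lig_coords: np.ndarray,
    lig: Ligand,
    weights: EnergyWeights,
) -> float:
    """Protein-ligand LJ + Coulomb over the interface subset."""
    subset = np.asarray(subset, dtype=int)
    if subset.size == 0:
        return 0.0
    pc = prot.coords[subset]
    A, B = _lj_ab(prot.vdw_radii[subset], prot.well_depths[subset],
                  lig.vdw_radii, lig.well_depths)
    qq = np.outer(prot.charges[subset], lig.charges)
    d = np.maximum(cdist(pc, np.asarray(lig_coords, float)), CLASH_DISTANCE)
    d6 = d ** 6
    lj = A / (d6 * d6) - B / d6
    coul = qq / (4.0 * d)
    return float(weights.w21 * lj.sum() + weights.w22 * coul.sum())


def _exclusion_pairs(lig: Ligand) -> tuple[np.ndarray, np.ndarray]:
    """Upper-triangle index arrays of ligand pairs beyond 1-2 and 1-3."""
    cache = getattr(lig, "_nb_pairs", None)
    if cache is not None:
        return cache
    n = len(lig.atoms)
    g = lig.bond_graph()
    order = [a.index for a in lig.atoms]
    pos = {idx: p for p, idx in enumerate(order)}
    near = np.zeros((n, n), dtype=bool)
    for src, lengths in nx.all_pairs_shortest_path_length(g, cutoff=2):
        for dst, L in lengths.items():
            if L >= 1:
                near[pos[src], pos[dst]] = True
    iu, ju = np.triu_indices(n, k=1)
    keep = ~near[iu, ju]
    pairs = (iu[keep], ju[keep])
    lig._nb_pairs = pairs
    return pairs


def _all_pairs(n: int) -> tuple[np.ndarray, np.ndarray]:
    return np.triu_indices(n, k=1)


def e_inter(
    lig_coords: np.ndarray,
    lig: Ligand,
    weights: EnergyWeights | None = None,
    *,
    literal_pairs: bool = False,
) -> float:
    """Intra-ligand Lennard-Jones over nonbonded atom pairs.

    ``literal_pairs=True`` sums every i != j pair including bonded ones
    (which are then deep in the repulsive wall and clamp-limited).
    """
    coords = np.asarray(lig_coords, dtype=float)
    n = len(lig.atoms)
    if n < 2:
        return 0.0
    iu, ju = _all_pairs(n) if literal_pairs else _exclusion_pairs(lig)
    if iu.size == 0:
        return 0.0
    r = lig.vdw_radii
    eps = lig.well_depths
    R = r[iu] + r[ju]
    e = np.sqrt(eps[iu] * eps[ju])
    R6 = R ** 6
    A = e * R6 * R6
    B = 2.0 * e * R6
    s = np.maximum(np.linalg.norm(coords[iu] - coords[ju], axis=1), CLASH_DISTANCE)
    s6 = s ** 6
    return float((A / (s6 * s6) - B / s6).sum())


def e_dis(pose_center, local_center, c_lim: float) -> float:
    """Flat-bottom centroid restraint: 0 inside c_lim, the distance at/beyond."""
    if c_lim <= 0:
        raise ParameterError("c_lim must be positive")
    d = float(np.linalg.norm(np.asarray(pose_center, float) - np.asarray(local_center, float)))
    return 0.0 if d < c_lim else d


# --- composite model -----------------------------------------------------

class EnergyModel:
    """Precomputed evaluator of the composite energy for one docking arena.

    Freezes the local map (centered CC reference vector), the interface
    protein subset with pairwise LJ/Coulomb coefficients, and the ligand's
    internal nonbonded pair list, then evaluates poses (coordinate arrays)
    quickly and deterministically.
    """

    def __init__(
        self,
        prot: Protein | None,
        lig: Ligand,
        local: LocalMap,
        weights: EnergyWeights | None = None,
        *,
        literal_pairs: bool = False,
    ):
        from .structio import ligand_diameter

        self.weights = weights or EnergyWeights()
        self.lig = lig
        self.local = local
        if lig.c_lim is None:
            ligand_diameter(lig)
        self.c_lim = float(lig.c_lim)
        self.c0 = np.asarray(local.center, dtype=float)
        res = local.resolution
        if res is None:
            raise ParameterError("local map has no resolution; set it on the parent grid")
        self._resolution = res
        self._masses = lig.masses
        # cached local-map geometry for the fast CC path; arithmetic is kept
        # identical to density.simulate_density/compute_cc so that breakdowns
        # decompose exactly into the standalone term functions
        w_kernel = kernel_width(res)
        self._k = math.pi / w_kernel
        self._peak = self._k ** 3
        self._r_cut = math.sqrt(-math.log(1e-8)) / self._k
        self._axes = [
            local.origin[i] + local.spacing * np.arange(local.dims[i])
            for i in range(3)
        ]
        exp_vec = local.values.ravel().astype(float)
        self._exp_centered = exp_vec - exp_vec.mean()
        self._exp_sq = float(np.dot(self._exp_centered, self._exp_centered))
        # interface protein subset
        if prot is not None:
            self.subset = select_interface_atoms(prot, local, lig)
            pc = prot.coords[self.subset]
            self._pc = pc
            self._A, self._B = _lj_ab(
                prot.vdw_radii[self.subset], prot.well_depths[self.subset],
                lig.vdw_radii, lig.well_depths,
            )
            self._qq = np.outer(prot.charges[self.subset], lig.charges)
        else:
            self.subset = np.array([], dtype=int)
            self._pc = np.zeros((0, 3))
        # ligand internal pairs
        n = len(lig.atoms)
        iu, ju = _all_pairs(n) if literal_pairs else _exclusion_pairs(lig)
        self._iu, self._ju = iu, ju
        r, epsv = lig.vdw_radii, lig.well_depths
        R6 = (r[iu] + r[ju]) ** 6
        e = np.sqrt(epsv[iu] * epsv[ju])
        self._Ai = e * R6 * R6
        self._Bi = 2.0 * e * R6

    def cc(self, coords: np.ndarray) -> float:
        """CC of a pose against the local-map region.

        Reproduces :func:`dockem.density.ligand_region_cc` bit-for-bit (same
        kernel windows and summation order) with the lattice precomputed.
        """
        values = np.zeros(self.local.dims, dtype=float)
        axes = self._axes
        k, peak, r_cut = self._k, self._peak, self._r_cut
        for xi, mi in zip(coords, self._masses):
            lo = [int(np.searchsorted(axes[a], xi[a] - r_cut, side="left"))
                  for a in range(3)]
            hi = [int(np.searchsorted(axes[a], xi[a] + r_cut, side="right"))
                  for a in range(3)]
            if any(l >= h for l, h in zip(lo, hi)):
                continue
            d2 = (
                ((axes[0][lo[0]:hi[0]] - xi[0]) ** 2)[:, None, None]
                + ((axes[1][lo[1]:hi[1]] - xi[1]) ** 2)[None, :, None]
                + ((axes[2][lo[2]:hi[2]] - xi[2]) ** 2)[None, None, :]
            )
            values[lo[0]:hi[0], lo[1]:hi[1], lo[2]:hi[2]] += \
                mi * peak * np.exp(-(k * k) * d2)
        x = values.ravel()
        x = x - x.mean()
        nx_ = float(np.dot(x, x))
        if nx_ <= 0.0 or self._exp_sq <= 0.0:
            return 0.0
        return float(np.dot(x, self._exp_centered) / math.sqrt(nx_ * self._exp_sq))

    def breakdown(self, coords: np.ndarray) -> EnergyBreakdown:
        coords = np.asarray(coords, dtype=float)
        w = self.weights
        cc = self.cc(coords)
        ecc = 1.0 - cc
        # protein-ligand term
        if self._pc.shape[0]:
            d = np.maximum(cdist(self._pc, coords), CLASH_DISTANCE)
            d6 = d ** 6
            eintra = float(
                w.w21 * (self._A / (d6 * d6) - self._B / d6).sum()
                + w.w22 * (self._qq / (4.0 * d)).sum()
            )
        else:
            eintra = 0.0
        # intra-ligand term
        if self._iu.size:
            s = np.maximum(
                np.linalg.norm(coords[self._iu] - coords[self._ju], axis=1),
                CLASH_DISTANCE,
            )
            s6 = s ** 6
            einter = float((self._Ai / (s6 * s6) - self._Bi / s6).sum())
        else:
            einter = 0.0
        edis = e_dis(coords.mean(axis=0), self.c0, self.c_lim)
        total = w.w1 * ecc + w.w2 * eintra + w.w3 * einter + w.w4 * edis
        return EnergyBreakdown(e_cc=ecc, e_intra=eintra, e_inter=einter,
                               e_dis=edis, total=total, cc=cc)

    __call__ = breakdown


def e_total(
    pose_coords: np.ndarray,
    prot: Protein | None,
    local: LocalMap,
    lig: Ligand,
    weights: EnergyWeights | None = None,
    *,
    literal_pairs: bool = False,
) -> EnergyBreakdown:
    """One-shot composite energy of a pose (see :class:`EnergyModel`)."""
    model = EnergyModel(prot, lig, local, weights, literal_pairs=literal_pairs)
    return model.breakdown(np.asarray(pose_coords, dtype=float))
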