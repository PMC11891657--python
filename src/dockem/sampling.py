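"""Monte Carlo moves and the replica-exchange driver.

A pose is a rigid transform (translation + unit quaternion about the
molecule centroid) plus one torsion angle per rotatable bond applied to a
fixed reference conformation. Replicas run independent Metropolis chains
on a geometric temperature ladder T_i = T_min (T_max/T_min)^((i-1)/(N-1));
every ``local_steps_per_swap`` local moves, neighboring replicas attempt a
configuration exchange with probability

    min{1, exp((E_j - E_i) (1/(K T_j) - 1/(K T_i)))}.

Swaps exchange poses between temperature slots, never create or destroy
them. All randomness flows from one seed through independent per-replica
streams, so runs are bit-reproducible.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np
from scipy.spatial.transform import Rotation

from .errors import MoveUnavailableError, ParameterError
from .structio import Ligand

__all__ = [
    "TorsionTopology",
    "Pose",
    "Replica",
    "Schedule",
    "RemcResult",
    "temperature_ladder",
    "swap_probability",
    "metropolis_accept",
    "propose_rigid_move",
    "propose_torsion_move",
    "random_orientation",
    "run_remc",
]

IDENTITY_QUAT = np.array([0.0, 0.0, 0.0, 1.0])


class TorsionTopology:
    """Per-ligand rotatable-bond machinery.

    For each rotatable bond the *distal* fragment is the smaller of the two
    components obtained by deleting the bond (tie broken toward the second
    bond atom); a torsion move rotates exactly those atoms about the bond
    axis, so bond lengths and the bond-adjacent angles are untouched.
    Atom indices here are 0-based positions into the coordinate array.
    """

    def __init__(self, lig: Ligand):
        from .structio import detect_rotatable_bonds

        if not lig.rotatable_bonds and lig.bonds:
            detect_rotatable_bonds(lig)
        g = lig.bond_graph()
        pos = {a.index: p for p, a in enumerate(lig.atoms)}
        self.axes: list[tuple[int, int, np.ndarray]] = []
        for b in lig.rotatable_bonds:
            h = g.copy()
            h.remove_edge(b.atom1, b.atom2)
            comp1 = nx.node_connected_component(h, b.atom1)
            comp2 = nx.node_connected_component(h, b.atom2)
            if len(comp2) <= len(comp1):
                anchor, moving, distal = b.atom1, b.atom2, comp2
            else:
                anchor, moving, distal = b.atom2, b.atom1, comp1
            idx = np.array(sorted(pos[i] for i in distal), dtype=int)
            self.axes.append((pos[anchor], pos[moving], idx))

    @property
    def n_torsions(self) -> int:
        return len(self.axes)

    def apply(self, coords: np.ndarray, angles_deg: np.ndarray) -> np.ndarray:
        """Rotate each distal fragment about its bond axis by its angle."""
        out = np.array(coords, dtype=float, copy=True)
        for (a, b, distal), angle in zip(self.axes, angles_deg):
            if angle == 0.0:
                continue
            axis = out[b] - out[a]
            norm = np.linalg.norm(axis)
            if norm < 1e-12:
                continue
            rot = Rotation.from_rotvec(axis / norm * math.radians(angle))
            out[distal] = rot.apply(out[distal] - out[a]) + out[a]
        return out


@dataclass(frozen=True)
class Pose:
    """Rigid transform + torsions applied to a reference conformation.

    Realized coordinates are: rotate ``reference_coords`` about their
    centroid by the quaternion and place that centroid at ``translation``,
    then apply the torsion angles in the world frame. Torsions move only
    the distal fragment of their bond, so the anchored fragment stays put
    in the map frame; the realized centroid c_i therefore equals
    ``translation`` exactly only while all torsions are zero.
    """

    translation: np.ndarray
    quaternion: np.ndarray
    torsions: np.ndarray
    reference_coords: np.ndarray
    topology: TorsionTopology

    def __post_init__(self) -> None:
        object.__setattr__(self, "translation", np.asarray(self.translation, float))
        q = np.asarray(self.quaternion, dtype=float)
        n = np.linalg.norm(q)
        if abs(n - 1.0) > 1e-9:
            if n <= 0:
                raise ParameterError("zero quaternion")
            q = q / n
        object.__setattr__(self, "quaternion", q)
        object.__setattr__(self, "torsions", np.asarray(self.torsions, dtype=float))

    @classmethod
    def initial(cls, lig: Ligand, topology: TorsionTopology | None = None) -> "Pose":
        ref = lig.coords
        topo = topology or TorsionTopology(lig)
        return cls(
            translation=ref.mean(axis=0),
            quaternion=IDENTITY_QUAT.copy(),
            torsions=np.zeros(topo.n_torsions),
            reference_coords=ref,
            topology=topo,
        )

    def coords(self) -> np.ndarray:
        centered = self.reference_coords - self.reference_coords.mean(axis=0)
        rot = Rotation.from_quat(self.quaternion)
        rigid = rot.apply(centered) + self.translation
        if self.torsions.size and np.any(self.torsions):
            return self.topology.apply(rigid, self.torsions)
        return rigid

    @property
    def centroid(self) -> np.ndarray:
        """Centroid of the realized conformation (c_i in the restraint)."""
        return self.coords().mean(axis=0)


@dataclass
class Replica:
    """One chain of the replica-exchange ensemble (temperature fixed to slot)."""

    pose: Pose
    temperature: float
    energy: object  # EnergyBreakdown or float
    rng: np.random.Generator
    best_pose: Pose | None = None
    best_energy: object | None = None
    active: bool = True
    diagnostic: str = ""


@dataclass(frozen=True)
class Schedule:
    """Replica-exchange schedule.

    ``local_steps_per_swap`` local Metropolis moves run in every replica
    between successive exchange attempts; ``total_sweeps`` is the number of
    such swap rounds.
    """

    N: int = 20
    t_min: float = 0.01
    t_max: float = 1.0
    local_steps_per_swap: int = 500
    total_sweeps: int = 20

    def __post_init__(self) -> None:
        if self.N < 2:
            raise ParameterError("at least two replicas are required")
        if not (0 < self.t_min < self.t_max):
            raise ParameterError("need 0 < t_min < t_max")
        if self.local_steps_per_swap < 1 or self.total_sweeps < 1:
            raise ParameterError("schedule lengths must be positive")


def temperature_ladder(sched: Schedule) -> np.ndarray:
    """Geometric ladder T_i = T_min (T_max/T_min)^((i-1)/(N-1)), i = 1..N."""
    i = np.arange(sched.N, dtype=float)
    return sched.t_min * (sched.t_max / sched.t_min) ** (i / (sched.N - 1))


def swap_probability(e_i: float, e_j: float, t_i: float, t_j: float, K: float = 1.0) -> float:
    """Replica-exchange acceptance probability for configurations i and j."""
    if t_i <= 0 or t_j <= 0 or K <= 0:
        raise ParameterError("temperatures and K must be positive")
    arg = (e_j - e_i) * (1.0 / (K * t_j) - 1.0 / (K * t_i))
    if arg >= 0:
        return 1.0
    return math.exp(max(arg, -700.0))


def metropolis_accept(
    e_old: float, e_new: float, temperature: float,
    rng: np.random.Generator, K: float = 1.0,
) -> bool:
    """Metropolis criterion at K-scaled temperature.

    Downhill (or equal) moves are always accepted and consume no random
    draw; uphill moves consume exactly one uniform draw.
    """
    if temperature <= 0:
        raise ParameterError("temperature must be positive")
    if e_new <= e_old:
        return True
    return bool(rng.random() < math.exp(max(-(e_new - e_old) / (K * temperature), -700.0)))


# --- move proposals ------------------------------------------------------

def _uniform_in_ball(rng: np.random.Generator, radius: float) -> np.ndarray:
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    if n < 1e-12:
        return np.zeros(3)
    return v / n * radius * rng.random() ** (1.0 / 3.0)


def random_orientation(rng: np.random.Generator) -> np.ndarray:
    """Uniformly random unit quaternion (large-scale rotation)."""
    q = rng.standard_normal(4)
    return q / np.linalg.norm(q)


def propose_rigid_move(
    pose: Pose, max_trans: float, max_rot_deg: float, rng: np.random.Generator
) -> Pose:
    """Perturb the rigid transform: translation uniform in a ball of
    ``max_trans``, rotation about a uniform random axis by an angle uniform
    in [0, max_rot_deg]. Torsions are untouched."""
    if max_trans < 0 or max_rot_deg < 0:
        raise ParameterError("move step sizes must be non-negative")
    t = pose.translation + _uniform_in_ball(rng, max_trans)
    axis = rng.standard_normal(3)
    n = np.linalg.norm(axis)
    angle = math.radians(rng.uniform(0.0, max_rot_deg)) if max_rot_deg > 0 else 0.0
    if n > 1e-12 and angle != 0.0:
        dq = Rotation.from_rotvec(axis / n * angle)
        q = (dq * Rotation.from_quat(pose.quaternion)).as_quat()
    else:
        q = pose.quaternion
    return replace(pose, translation=t, quaternion=q)


def _wrap_angle(a: float) -> float:
    return (a + 180.0) % 360.0 - 180.0


def propose_torsion_move(
    pose: Pose, rng: np.random.Generator, max_step: float = 180.0
) -> Pose:
    """Rotate one uniformly chosen rotatable bond by a uniform angle in
    [-max_step, max_step] degrees (default the full [-180, 180] range; the
    distal fragment moves rigidly about the bond axis)."""
    n = pose.topology.n_torsions
    if n == 0:
        raise MoveUnavailableError("ligand has no rotatable bonds")
    k = int(rng.integers(n))
    delta = rng.uniform(-max_step, max_step)
    torsions = pose.torsions.copy()
    torsions[k] = _wrap_angle(torsions[k] + delta)
    return replace(pose, torsions=torsions)


# --- REMC driver ---------------------------------------------------------

@dataclass
class RemcResult:
    replicas: list[Replica]
    best_poses: list[Pose]
    best_energies: list[object]
    trace: list[list[float]]  # per replica, per sweep: current scalar energy
    quarantined: list[int] = field(default_factory=list)


def _scalar(e) -> float:
    return float(getattr(e, "total", e))


def run_remc(
    initial_poses: list[Pose],
    energy_fn,
    sched: Schedule,
    move_fn,
    seed: int | None = None,
    K: float = 1.0,
) -> RemcResult:
    """Replica-exchange Metropolis sampling.

    ``energy_fn(pose) -> EnergyBreakdown | float`` and
    ``move_fn(pose, rng) -> Pose`` define the system. Adjacent slot pairs
    alternate even/odd pairing across sweeps. A replica whose energy turns
    non-finite is quarantined (excluded from moves and swaps) and reported;
    the run continues. Returns the lowest-energy pose visited per slot.
    """
    if len(initial_poses) != sched.N:
        raise ParameterError(
            f"expected {sched.N} initial poses, got {len(initial_poses)}"
        )
    ladder = temperature_ladder(sched)
    streams = np.random.SeedSequence(seed).spawn(sched.N + 1)
    swap_rng = np.random.default_rng(streams[-1])
    replicas: list[Replica] = []
    for pose, temp, stream in zip(initial_poses, ladder, streams):
        e = energy_fn(pose)
        rep = Replica(pose=pose, temperature=float(temp), energy=e,
                      rng=np.random.default_rng(stream))
        if not math.isfinite(_scalar(e)):
            rep.active = False
            rep.diagnostic = "non-finite energy at initialization"
        else:
            rep.best_pose, rep.best_energy = pose, e
        replicas.append(rep)

    trace: list[list[float]] = [[] for _ in replicas]
    for sweep in range(sched.total_sweeps):
        for rep in replicas:
            if not rep.active:
                continue
            for _ in range(sched.local_steps_per_swap):
                try:
                    prop = move_fn(rep.pose, rep.rng)
                except MoveUnavailableError:
                    continue
                e_new = energy_fn(prop)
                if not math.isfinite(_scalar(e_new)):
                    rep.active = False
                    rep.diagnostic = f"non-finite energy at sweep {sweep}"
                    break
                if metropolis_accept(_scalar(rep.energy), _scalar(e_new),
                                     rep.temperature, rep.rng, K):
                    rep.pose, rep.energy = prop, e_new
                    if _scalar(e_new) < _scalar(rep.best_energy):
                        rep.best_pose, rep.best_energy = prop, e_new
        # exchange phase: alternating even/odd adjacent pairing
        for i in range(sweep % 2, sched.N - 1, 2):
            a, b = replicas[i], replicas[i + 1]
            if not (a.active and b.active):
                continue
            p = swap_probability(_scalar(a.energy), _scalar(b.energy),
                                 a.temperature, b.temperature, K)
            if swap_rng.random() < p:
                a.pose, b.pose = b.pose, a.pose
                a.energy, b.energy = b.energy, a.energy
                for rep in (a, b):
                    if _scalar(rep.energy) < _scalar(rep.best_energy):
                        rep.best_pose, rep.best_energy = rep.pose, rep.energy
        for rep, tr in zip(replicas, trace):
            tr.append(_scalar(rep.energy) if rep.active else math.nan)

    return RemcResult(
        replicas=replicas,
        best_poses=[r.best_pose for r in replicas],
        best_energies=[r.best_energy for r in replicas],
        trace=trace,
        quarantined=[i for i, r in enumerate(replicas) if not r.active],
    )
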