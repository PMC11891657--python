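"""The docking workflow: align, position the local map, dock, refine, select.

Stages
------
1. *align*: rigid-body fit of the receptor into the full map by maximizing
   the protein-vs-map CC (skipped for pre-fitted inputs).
2. *initial center*: the binding-site center (given coordinate, or the
   centroid of the named site residues) seeds the local-map center c_0.
3. *position local map*: a 500-step single-chain Monte Carlo fit of the
   ligand into an initial cube of edge twice the ligand diameter, scored by
   w1*E_CC + w2*E_intra; the best pose's centroid becomes the refined c_0
   and the arena shrinks to a cube of edge one ligand diameter.
4. *rigid dock*: 20-replica REMC over rigid poses under the full composite
   energy; each replica starts at c_0 with a random large-scale orientation
   and a small random translation.
5. *flexible refine*: REMC seeded with the rigid winners; each local step
   is a rigid perturbation followed by one torsion move.
6. *select*: lowest total energy wins (ties: higher CC, then lower slot).
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field, replace as _dc_replace

import numpy as np
from scipy.spatial.transform import Rotation

import yaml

from .density import DensityGrid, LocalMap, extract_local_map, read_mrc, write_mrc
from .energy import EnergyBreakdown, EnergyModel, EnergyWeights
from .errors import (
    AlignmentError,
    DockemError,
    ParameterError,
    SelectionError,
    SiteError,
)
from .sampling import (
    Pose,
    Schedule,
    TorsionTopology,
    metropolis_accept,
    propose_rigid_move,
    propose_torsion_move,
    random_orientation,
    run_remc,
)
from .structio import (
    Ligand,
    Protein,
    assign_parameters,
    detect_rotatable_bonds,
    ligand_diameter,
    read_mol2,
    read_pdb,
    write_mol2,
    write_pdb,
)

__all__ = [
    "DockingConfig",
    "DockingRun",
    "RigidTransform",
    "align_protein_to_map",
    "initial_local_center",
    "position_local_map",
    "rigid_dock",
    "flexible_refine",
    "select_final_pose",
    "run_dockem",
]


@dataclass(frozen=True)
class DockingConfig:
    """All tunable run parameters with their defaults.

    Step sizes are in angstroms / degrees. ``replicas``/``steps_per_swap``
    follow the standard protocol (20 replicas, exchange every 500 local
    moves); ``sweeps`` is the number of exchange rounds per stage.
    """

    weights: EnergyWeights = field(default_factory=EnergyWeights)
    replicas: int = 20
    sweeps: int = 20
    steps_per_swap: int = 500
    t_min: float = 0.01
    t_max: float = 1.0
    rigid_max_trans: float = 0.5
    rigid_max_rot: float = 15.0
    reorient_prob: float = 0.1       # chance a rigid move redraws the full orientation
    torsion_max_step: float = 180.0  # half-width of the torsion move (deg)
    init_max_trans: float = 1.0       # small-scale random start translations
    position_steps: int = 500         # local-map centering MC length
    position_max_trans: float = 1.0
    position_max_rot: float = 30.0
    align_replicas: int = 4
    align_sweeps: int = 5
    align_steps_per_swap: int = 50
    align_max_trans: float = 1.0
    align_max_rot: float = 10.0
    align_stride: float = 2.0         # coarse translation scan stride
    include_amide: bool = False
    literal_pairs: bool = False
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str) -> "DockingConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        wkeys = {f.name for f in dataclasses.fields(EnergyWeights)}
        wraw = {k: v for k, v in raw.pop("weights", {}).items() if k in wkeys}
        known = {f.name for f in dataclasses.fields(cls)} - {"weights"}
        bad = set(raw) - known
        if bad:
            raise ParameterError(f"unknown config keys: {sorted(bad)}")
        return cls(weights=EnergyWeights(**wraw), **raw)

    def schedule(self) -> Schedule:
        return Schedule(N=self.replicas, t_min=self.t_min, t_max=self.t_max,
                        local_steps_per_swap=self.steps_per_swap,
                        total_sweeps=self.sweeps)

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        return d


@dataclass(frozen=True)
class RigidTransform:
    """x -> rotation @ (x - pivot) + translation."""

    rotation: np.ndarray
    translation: np.ndarray
    pivot: np.ndarray

    @classmethod
    def identity(cls, pivot=None) -> "RigidTransform":
        p = np.zeros(3) if pivot is None else np.asarray(pivot, float)
        return cls(rotation=np.eye(3), translation=p.copy(), pivot=p)

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return (np.asarray(coords, float) - self.pivot) @ self.rotation.T + self.translation

    @property
    def translation_magnitude(self) -> float:
        return float(np.linalg.norm(self.translation - self.pivot))

    @property
    def rotation_angle_deg(self) -> float:
        return float(np.degrees(np.linalg.norm(
            Rotation.from_matrix(self.rotation).as_rotvec())))


# --- stage 1: protein-map alignment --------------------------------------

class _MapFitEnergy:
    """1 - CC between a rigidly transformed molecule and a full map."""

    def __init__(self, coords: np.ndarray, masses: np.ndarray, grid: DensityGrid):
        from .density import simulate_density, compute_cc

        self._coords = coords
        self._masses = masses
        self._grid = grid
        if grid.resolution is None:
            raise ParameterError("map has no resolution; pass one to read_mrc")
        exp = grid.values.ravel()
        if float(np.var(exp)) <= 0.0:
            raise AlignmentError("map has zero variance; cannot align against it")
        self._sim = simulate_density
        self._cc = compute_cc

    def __call__(self, pose: Pose) -> float:
        coords = pose.coords()
        calc = self._sim(coords, self._grid.resolution, self._grid.spacing,
                         self._grid.origin, self._grid.dims, masses=self._masses)
        return 1.0 - float(self._cc(calc.values, self._grid.values))


def align_protein_to_map(
    prot: Protein,
    grid: DensityGrid,
    config: DockingConfig | None = None,
    seed: int | None = None,
    *,
    prefitted: bool = False,
) -> tuple[RigidTransform, Protein]:
    """Rigid-body fit of the receptor into the full map by CC maximization.

    A coarse scan of centroid translations (stride ``align_stride`` A over
    the map extent) seeds a short rigid REMC refinement. With
    ``prefitted=True`` the identity transform is returned unchanged.
    """
    config = config or DockingConfig()
    coords = prot.coords
    centroid = coords.mean(axis=0)
    if prefitted:
        return RigidTransform.identity(centroid), prot
    masses = prot.masses
    energy = _MapFitEnergy(coords, masses, grid)

    # coarse translation scan of the centroid across the map extent
    lo, hi = grid.bounding_box()
    topo = _EmptyTopology()
    best_t, best_e = centroid, None
    for cand in _translation_candidates(lo, hi, centroid, config.align_stride):
        pose = Pose(translation=cand, quaternion=[0, 0, 0, 1.0],
                    torsions=np.zeros(0), reference_coords=coords, topology=topo)
        e = energy(pose)
        if best_e is None or e < best_e:
            best_t, best_e = cand, e

    sched = Schedule(N=config.align_replicas, t_min=config.t_min,
                     t_max=config.t_max,
                     local_steps_per_swap=config.align_steps_per_swap,
                     total_sweeps=config.align_sweeps)
    initial = [
        Pose(translation=best_t, quaternion=[0, 0, 0, 1.0], torsions=np.zeros(0),
             reference_coords=coords, topology=topo)
        for _ in range(sched.N)
    ]
    move = lambda pose, rng: propose_rigid_move(
        pose, config.align_max_trans, config.align_max_rot, rng)
    result = run_remc(initial, energy, sched, move, seed=seed, K=config.weights.K)
    idx = int(np.argmin([float(e) for e in result.best_energies]))
    best = result.best_poses[idx]
    rot = Rotation.from_quat(best.quaternion).as_matrix()
    transform = RigidTransform(rotation=rot, translation=best.translation,
                               pivot=centroid)
    return transform, prot.with_coords(transform.apply(coords))


class _EmptyTopology:
    """Torsion topology of a rigid body (no rotatable bonds)."""

    axes: list = []
    n_torsions = 0

    def apply(self, coords, angles):  # pragma: no cover - never called
        return coords


def _translation_candidates(lo, hi, centroid, stride):
    yield centroid.copy()
    axes = [np.arange(lo[a], hi[a] + 1e-9, stride) for a in range(3)]
    for x in axes[0]:
        for y in axes[1]:
            for z in axes[2]:
                yield np.array([x, y, z])


# --- stage 2: binding-site center ----------------------------------------

def initial_local_center(site_spec, prot: Protein) -> np.ndarray:
    """Initial local-map center from a coordinate or a residue list.

    A 3-sequence of numbers passes through unchanged; otherwise the spec is
    a list of residues ("A:45" strings or (chain, resid) pairs) whose atom
    centroid (in the aligned frame) is returned.
    """
    arr = np.asarray(site_spec, dtype=object)
    if arr.shape == (3,) and all(isinstance(v, (int, float, np.floating)) for v in arr):
        return np.asarray(site_spec, dtype=float)
    wanted = []
    for item in site_spec:
        if isinstance(item, str):
            chain, _, resid = item.partition(":")
            if not resid:
                raise SiteError(f"bad residue spec {item!r}; expected 'CHAIN:RESID'")
            wanted.append((chain, int(resid)))
        else:
            chain, resid = item
            wanted.append((str(chain), int(resid)))
    positions: list[int] = []
    missing = []
    index = {(r.chain, r.resid): r for r in prot.residues}
    for key in wanted:
        if key in index:
            positions.extend(index[key].atom_positions)
        else:
            missing.append(key)
    if missing:
        raise SiteError(f"residues not found in receptor: {missing}")
    return prot.coords[positions].mean(axis=0)


# --- stage 3: local-map positioning --------------------------------------

def position_local_map(
    lig: Ligand,
    grid: DensityGrid,
    c0_init,
    prot: Protein | None,
    weights: EnergyWeights | None = None,
    seed: int | None = None,
    config: DockingConfig | None = None,
) -> tuple[LocalMap, Pose, dict]:
    """Fit the ligand near the site and refine the local-map center.

    Extracts an initial cube of edge 2x the ligand diameter at the given
    center, runs ``position_steps`` single-chain Metropolis steps of rigid
    ligand moves at T_min scored by w1*E_CC + w2*E_intra, then re-centers a
    cube of edge 1x the diameter on the best pose's centroid.
    Returns (refined local map, best pose, stage info).
    """
    config = config or DockingConfig()
    weights = weights or config.weights
    c0_init = np.asarray(c0_init, dtype=float)
    diameter = lig.diameter if lig.diameter is not None else ligand_diameter(lig)
    local0 = extract_local_map(grid, c0_init, 2.0 * diameter)
    stage_weights = EnergyWeights(w1=weights.w1, w2=weights.w2, w3=0.0, w4=0.0,
                                  w21=weights.w21, w22=weights.w22, K=weights.K)
    model = EnergyModel(prot, lig, local0, stage_weights,
                        literal_pairs=config.literal_pairs)
    topo = TorsionTopology(lig)
    pose = Pose(translation=c0_init, quaternion=[0, 0, 0, 1.0],
                torsions=np.zeros(topo.n_torsions),
                reference_coords=lig.coords, topology=topo)
    rng = np.random.default_rng(np.random.SeedSequence(seed))
    e = model.breakdown(pose.coords())
    best_pose, best_e = pose, e
    for _ in range(config.position_steps):
        prop = propose_rigid_move(pose, config.position_max_trans,
                                  config.position_max_rot, rng)
        e_new = model.breakdown(prop.coords())
        if metropolis_accept(e.total, e_new.total, config.t_min, rng, weights.K):
            pose, e = prop, e_new
            if e_new.total < best_e.total:
                best_pose, best_e = prop, e_new
    c0_refined = best_pose.centroid
    refined = extract_local_map(grid, c0_refined, diameter)
    info = {
        "c0_initial": c0_init.tolist(),
        "c0_refined": np.asarray(c0_refined, float).tolist(),
        "center_shift": float(np.linalg.norm(c0_refined - c0_init)),
        "best_energy": best_e.as_dict(),
        "steps": config.position_steps,
    }
    return refined, best_pose, info


# --- stages 4-6: docking, refinement, selection --------------------------

def _stage_models(prot, lig, local, config):
    model = EnergyModel(prot, lig, local, config.weights,
                        literal_pairs=config.literal_pairs)
    return model


def _rigid_move_fn(config: DockingConfig):
    """Small rigid perturbations, mixed with occasional full reorientations.

    Torsion moves already jump the full [-180, 180] range, so orientation
    space gets the same treatment with probability ``reorient_prob``; this
    lets chains cross the large rotation barriers between map-degenerate
    orientations. Disabled whenever the rotation step size is zero so a
    zero-move-size schedule leaves poses untouched.
    """

    def move(pose, rng):
        out = propose_rigid_move(pose, config.rigid_max_trans,
                                 config.rigid_max_rot, rng)
        if (config.rigid_max_rot > 0 and config.reorient_prob > 0
                and rng.random() < config.reorient_prob):
            out = _dc_replace(out, quaternion=random_orientation(rng))
        return out

    return move


def rigid_dock(
    lig: Ligand,
    local: LocalMap,
    prot: Protein | None,
    config: DockingConfig | None = None,
    seed: int | None = None,
) -> tuple[list[Pose], list[EnergyBreakdown]]:
    """REMC rigid docking inside the refined local map.

    Each replica starts with the ligand centroid at the local-map center,
    a uniformly random orientation, and a small random translation; local
    moves are rigid only. Returns the lowest-energy pose of each replica.
    """
    config = config or DockingConfig()
    model = _stage_models(prot, lig, local, config)
    topo = TorsionTopology(lig)
    sched = config.schedule()
    ss = np.random.SeedSequence(seed).spawn(2)
    init_rng = np.random.default_rng(ss[0])
    ref = lig.coords
    initial = []
    for _ in range(sched.N):
        q = random_orientation(init_rng)
        t = np.asarray(local.center, float) + _small_translation(init_rng, config.init_max_trans)
        initial.append(Pose(translation=t, quaternion=q,
                            torsions=np.zeros(topo.n_torsions),
                            reference_coords=ref, topology=topo))
    energy = lambda pose: model.breakdown(pose.coords())
    result = run_remc(initial, energy, sched, _rigid_move_fn(config),
                      seed=int(ss[1].generate_state(1)[0] % (2 ** 31)),
                      K=config.weights.K)
    poses = [p for p in result.best_poses if p is not None]
    energies = [e for e in result.best_energies if e is not None]
    return poses, energies


def _small_translation(rng, radius):
    v = rng.standard_normal(3)
    n = np.linalg.norm(v)
    return np.zeros(3) if n < 1e-12 else v / n * radius * rng.random() ** (1 / 3)


def flexible_refine(
    poses: list[Pose],
    lig: Ligand,
    local: LocalMap,
    prot: Protein | None,
    config: DockingConfig | None = None,
    seed: int | None = None,
) -> tuple[list[Pose], list[EnergyBreakdown], dict]:
    """Torsion-space refinement: each input pose seeds one REMC replica.

    A local move is a rigid perturbation followed by one random torsion
    rotation. With no rotatable bonds the stage degrades to rigid REMC and
    says so in the returned info. The running-minimum contract guarantees
    every output pose has energy <= its seed pose.
    """
    if not poses:
        raise SelectionError("flexible_refine needs at least one input pose")
    config = config or DockingConfig()
    model = _stage_models(prot, lig, local, config)
    n_rot = poses[0].topology.n_torsions
    info = {"rotatable_bonds": n_rot}
    if n_rot == 0:
        info["notice"] = "no rotatable bonds; refinement uses rigid moves only"
    sched = Schedule(N=len(poses), t_min=config.t_min, t_max=config.t_max,
                     local_steps_per_swap=config.steps_per_swap,
                     total_sweeps=config.sweeps)
    energy = lambda pose: model.breakdown(pose.coords())
    rigid_move = _rigid_move_fn(config)

    def move(pose, rng):
        out = rigid_move(pose, rng)
        if n_rot:
            out = propose_torsion_move(out, rng, config.torsion_max_step)
        return out

    result = run_remc(poses, energy, sched, move, seed=seed, K=config.weights.K)
    out_poses = [p for p in result.best_poses if p is not None]
    out_energies = [e for e in result.best_energies if e is not None]
    return out_poses, out_energies, info


def select_final_pose(
    poses: list[Pose], energies: list[EnergyBreakdown]
) -> tuple[Pose, EnergyBreakdown, list[dict]]:
    """Pick the lowest-total-energy pose; ties by higher CC, then lower slot."""
    if not poses:
        raise SelectionError("no poses to select from")
    order = sorted(range(len(poses)),
                   key=lambda i: (energies[i].total, -energies[i].cc, i))
    ranking = [
        {"replica": i, "rank": r, **energies[i].as_dict()}
        for r, i in enumerate(order)
    ]
    best = order[0]
    return poses[best], energies[best], ranking


# --- full run ------------------------------------------------------------

@dataclass
class DockingRun:
    """Everything a docking run produced, serializable to a report."""

    config: DockingConfig
    transform: RigidTransform
    protein: Protein
    ligand: Ligand
    grid: DensityGrid
    local_map: LocalMap
    stages: dict
    final_pose: Pose
    final_energy: EnergyBreakdown
    ranking: list[dict]

    @property
    def final_coords(self) -> np.ndarray:
        return self.final_pose.coords()

    def report(self) -> dict:
        return {
            "config": _jsonable(self.config.to_dict()),
            "alignment": {
                "translation_magnitude": self.transform.translation_magnitude,
                "rotation_angle_deg": self.transform.rotation_angle_deg,
            },
            "stages": _jsonable(self.stages),
            "final": {
                **self.final_energy.as_dict(),
                "centroid": self.final_pose.centroid.tolist(),
                "center_distance": float(np.linalg.norm(
                    self.final_pose.centroid - np.asarray(self.local_map.center))),
            },
            "ranking": _jsonable(self.ranking),
        }


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    return obj


def run_dockem(
    protein,
    ligand,
    grid,
    site,
    *,
    resolution: float | None = None,
    config: DockingConfig | None = None,
    prefitted: bool = False,
    out_dir: str | None = None,
) -> DockingRun:
    """Execute the full docking workflow.

    ``protein``/``ligand``/``grid`` may be in-memory objects or file paths
    (PDB, MOL2, MRC). ``site`` is a coordinate triple or a residue list.
    Stage outputs, energies, and the config echo are written to
    ``report.json`` (plus pose/structure/map files) when ``out_dir`` is set.
    """
    config = config or DockingConfig()
    prot = _load_protein(protein)
    lig = _load_ligand(ligand)
    grid = _load_grid(grid, resolution)
    if grid.resolution is None:
        raise ParameterError("map resolution is required (argument or header)")
    assign_parameters(prot)
    assign_parameters(lig)
    detect_rotatable_bonds(lig, include_amide=config.include_amide)
    ligand_diameter(lig)

    seeds = [int(s.generate_state(1)[0] % (2 ** 31))
             for s in np.random.SeedSequence(config.seed).spawn(4)]
    stages: dict = {"seed": config.seed}

    stage = "align"
    try:
        transform, prot_aligned = align_protein_to_map(
            prot, grid, config, seed=seeds[0], prefitted=prefitted)
        stages["align"] = {
            "prefitted": prefitted,
            "translation_magnitude": transform.translation_magnitude,
            "rotation_angle_deg": transform.rotation_angle_deg,
        }

        stage = "initial_center"
        c0 = initial_local_center(site, prot_aligned)
        stages["initial_center"] = {"c0": c0.tolist()}

        stage = "position_local_map"
        local, _, pos_info = position_local_map(
            lig, grid, c0, prot_aligned, config.weights, seed=seeds[1],
            config=config)
        stages["position_local_map"] = pos_info

        stage = "rigid_dock"
        rigid_poses, rigid_energies = rigid_dock(
            lig, local, prot_aligned, config, seed=seeds[2])
        stages["rigid_dock"] = {
            "poses": len(rigid_poses),
            "energies": [e.as_dict() for e in rigid_energies],
            "center_distances": [
                float(np.linalg.norm(p.centroid - np.asarray(local.center)))
                for p in rigid_poses
            ],
        }

        stage = "flexible_refine"
        refined_poses, refined_energies, flex_info = flexible_refine(
            rigid_poses, lig, local, prot_aligned, config, seed=seeds[3])
        stages["flexible_refine"] = {
            **flex_info,
            "energies": [e.as_dict() for e in refined_energies],
        }

        stage = "select"
        final_pose, final_energy, ranking = select_final_pose(
            refined_poses, refined_energies)
    except DockemError as exc:
        raise DockemError(f"stage {stage!r} failed: {exc}") from exc

    run = DockingRun(
        config=config, transform=transform, protein=prot_aligned, ligand=lig,
        grid=grid, local_map=local, stages=stages, final_pose=final_pose,
        final_energy=final_energy, ranking=ranking,
    )
    if out_dir is not None:
        _write_outputs(run, out_dir)
    return run


def _load_protein(obj) -> Protein:
    if isinstance(obj, Protein):
        return obj
    with open(obj) as fh:
        return read_pdb(fh.read())


def _load_ligand(obj) -> Ligand:
    if isinstance(obj, Ligand):
        return obj
    with open(obj) as fh:
        return read_mol2(fh.read())


def _load_grid(obj, resolution) -> DensityGrid:
    if isinstance(obj, DensityGrid):
        if resolution is not None:
            return _dc_replace(obj, resolution=resolution)
        return obj
    return read_mrc(obj, resolution=resolution)


def _write_outputs(run: DockingRun, out_dir: str) -> None:
    os.makedirs(out_dir, exist_ok=True)
    final_lig = run.ligand.with_coords(run.final_coords)
    with open(os.path.join(out_dir, "pose_final.mol2"), "w") as fh:
        fh.write(write_mol2(final_lig))
    with open(os.path.join(out_dir, "protein_aligned.pdb"), "w") as fh:
        fh.write(write_pdb(run.protein))
    local_grid = DensityGrid(values=np.array(run.local_map.values),
                             origin=run.local_map.origin,
                             spacing=run.local_map.spacing,
                             resolution=run.local_map.resolution)
    write_mrc(local_grid, os.path.join(out_dir, "localmap.mrc"))
    with open(os.path.join(out_dir, "report.json"), "w") as fh:
        json.dump(run.report(), fh, indent=2, sort_keys=True)
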