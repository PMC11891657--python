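# Methods

## Problem and model

`dockem` refines the pose of a small-molecule ligand inside the ligand
region of a cryo-EM density map. The inputs are a receptor structure
(PDB), a ligand with partial charges and a bond table (Tripos MOL2), a
density map (MRC/CCP4) with a stated nominal resolution R in Å, and a
binding-site hint (a coordinate or a residue list). The output is a
refined ligand pose plus a per-term energy report.

Sampling minimizes a composite energy over the pose variables
(rigid translation, rigid orientation, and one torsion angle per
rotatable bond):

```
E_total = w1·E_CC + w2·E_intra + w3·E_inter + w4·E_dis
```

* **E_CC = 1 − CC.** CC is the Pearson correlation, over the voxels of
  the *local* map (a cube around the binding site), between the
  experimental density and a density simulated from the current ligand
  pose. Each atom contributes an isotropic Gaussian with width
  `w = 2.4 + 0.8 R` Å:

  ```
  ρ_c(g) = Σ_i m_i (π/w)³ exp(−(π/w)² |x_i − x_g|²)
  ```

  evaluated at voxel centers with continuous atom coordinates (atoms are
  never snapped to the lattice). Kernels are truncated where they fall
  below 1e−8 of their peak; the error this introduces is far below the
  CC tolerances used anywhere in the package. If either voxel vector
  has zero variance (e.g. the pose left the map), CC is defined as 0 and
  flagged, so sampling continues with the worst map score instead of
  crashing.

* **E_intra**: protein–ligand interactions,
  `Σ w21 (A/d¹² − B/d⁶) + w22 q_i q_j / (4 d)`, with
  `A = εR¹²`, `B = 2εR⁶`, `R = r_i + r_j`, `ε = √(ε_i ε_j)` — so a pair
  at its minimum distance contributes exactly −ε. Parameters come from a
  per-element AMBER99-style table. Only *interface* protein atoms enter
  the sum: those whose distance to the local-map cube is strictly less
  than half the ligand diameter. The Coulomb term is kept in arbitrary
  units with every physical constant absorbed into `w22`.

* **E_inter**: the same Lennard-Jones form summed over intra-ligand atom
  pairs, excluding 1-2 (bonded) and 1-3 (angle) pairs. Without this
  exclusion every chemical bond would register as a severe clash and the
  native pose would not be low-energy; the exclusion is standard
  force-field practice. A `literal_pairs` switch restores the verbatim
  all-pairs sum for comparison. Note that 1-4 ring pairs are *not*
  excluded, so rigid ring systems carry a constant positive offset; this
  does not affect pose ranking because the offset is conformation-
  independent for rigid fragments.

* **E_dis**: a flat-bottom restraint on the pose centroid c_i — zero
  while `|c_i − c_0| < c_lim` (half the ligand's maximum inter-atomic
  distance), and equal to the center distance at or beyond it. It
  confines the search to the local-map neighborhood.

Distances in the physics terms are clamped below at 0.3 Å: Metropolis
sampling only needs finite, correctly ordered energies, and the clamp
prevents floating-point overflow in deep clashes.

### Weights

The method leaves all weights free. Defaults are
`w1 = 10, w2 = 0.1, w3 = 0.1, w4 = 1, w21 = 1, w22 = 1, K = 1`, chosen
so that the bounded map term (E_CC ∈ [0, 2]) and the clamped physics
terms have comparable magnitudes on the synthetic fixtures. They are
plain configuration (YAML/CLI), echoed into every run report; weight
sensitivity is a user-facing concern, not a hidden constant.

## Workflow

1. **Receptor–map alignment.** The receptor is rigidly fitted into the
   full map by maximizing the whole-protein CC: a coarse scan of
   centroid translations (2 Å stride over the map extent) seeds a short
   replica-exchange refinement (4 replicas × 5 sweeps × 50 steps, 1 Å /
   10° steps). Pre-fitted structures (the normal case for deposited
   EMDB models) skip this stage with `--prefitted`.
2. **Initial local center.** A given docking position passes through
   unchanged; a residue-list site becomes the centroid of those
   residues' atoms in the aligned frame.
3. **Local-map positioning.** A cube of edge 2× the ligand diameter is
   cut at the initial center; the ligand starts at the center and runs
   500 single-chain Metropolis steps of rigid moves (1 Å / 30°) at
   T = T_min under `w1·E_CC + w2·E_intra`. The best pose's centroid
   becomes the refined center c_0, and the arena shrinks to a cube of
   edge 1× the diameter. The local map is always a *view* of the parent
   grid — never a resample — so voxel values are bit-identical.
4. **Rigid docking.** Replica-exchange Monte Carlo (default 20
   replicas) under the full E_total. Each replica starts at c_0 with a
   uniformly random orientation and a small (≤1 Å) random translation.
   Temperatures follow the geometric ladder
   `T_i = T_min (T_max/T_min)^((i−1)/(N−1))` with T_min = 0.01,
   T_max = 1; every 500 local moves (configurable), adjacent replicas —
   alternating even/odd pairing per sweep — attempt a configuration
   swap with probability
   `min{1, exp((E_j − E_i)(1/(K T_j) − 1/(K T_i)))}`. Swaps exchange
   poses between temperature slots, never create or destroy them.
5. **Flexible refinement.** The lowest-energy pose of each rigid
   replica seeds one refinement replica. A local move is a rigid
   perturbation (0.5 Å / 15°) followed by one torsion move: a uniformly
   chosen rotatable bond rotated by a uniform angle in [−180°, 180°],
   moving only the distal fragment rigidly about the bond axis so all
   bond lengths and bond-adjacent angles are preserved exactly.
6. **Selection.** The pose with minimal E_total wins; ties break toward
   higher CC, then lower replica index. The full ranking is serialized.

Local Metropolis acceptance uses the same K·T scaling as the swap rule:
downhill moves are free, uphill moves accepted with probability
`exp(−ΔE/(K T))` consuming exactly one uniform draw.

### Rotatable bonds

A bond is rotatable when its MOL2 order token is `1`, it lies in no
ring (bridge test on the bond graph), and deleting it leaves two
fragments of at least two atoms each — rotating a terminal atom about
its own bond axis moves nothing. Amide (`am`) bonds are excluded by
default (`include_amide` switches them on); their rotation is hindered
in reality and the minimal reading of "single rotatable bonds" leaves
them out.

### Orientation mixing

Torsion moves span the full ±180° range, so torsion space mixes in one
step; incremental 15° rotations alone, by contrast, take hundreds of
accepted steps to cross between orientation basins. At 3 Å resolution a
ligand's flipped orientation can score almost as well as the true one,
and chains started there stall. Rigid moves therefore redraw the full
orientation with probability 0.1 (`reorient_prob`), which symmetrizes
the treatment of orientation and torsion space. The mixing component is
disabled whenever the rotation step size is zero, so a zero-move-size
schedule is exactly a no-op.

## Randomness and reproducibility

One master seed feeds a `numpy` `SeedSequence`; per-replica streams and
the swap stream are spawned children, and every stage of the pipeline
derives its own child seed. Identical (seed, config) inputs reproduce
trajectories and reports bit-for-bit; the seed is echoed in the report.

## Evaluation

The pose score is the **mapped (symmetry-corrected) RMSD**: the minimum
coordinate RMSD over all element-preserving bond-graph isomorphisms
between predicted and reference ligand, computed in the map frame
without superposition (a `superpose` flag offers Kabsch-aligned RMSD
for diagnostics). Isomorphisms are enumerated with VF2; heavy atoms
only by default, since hydrogen presence in MOL2 files varies. Tests
verify the search against exhaustive permutation enumeration on small
symmetric molecules. `success_rate` counts values strictly below a
threshold (3 Å by convention; 2 Å as the strict criterion).

## Synthetic fixture

`generate_fixture` builds a deterministic toy problem: an aromatic
six-carbon ring carrying O and N substituents placed asymmetrically
(so the bond graph has no spurious automorphisms), plus an alkyl chain
— a chain of length L contributes L−1 rotatable bonds; the default is
11 heavy atoms and 2 rotatable bonds, with bond lengths 1.36–1.52 Å and
a small seeded coordinate jitter (σ = 0.02 Å). The receptor is a shell
of ~30 pocket pseudo-atoms sampled on a sphere 3.5 Å clear of the
ligand, grouped into 4-atom residues, with table-default charges. The
map is simulated from protein + ligand at the requested resolution
(default R = 3 Å, spacing 1.0 Å — the spacing is a package default; it
is configurable).

What the fixture does *not* emulate: experimental map noise and
B-factor heterogeneity, solvent contributions, real pocket chemistry
and induced fit, hydrogens, and crystallographic-scale ligand
diversity. Recovery results on the fixture therefore demonstrate the
correctness and internal consistency of the scoring and sampling
machinery — not benchmark-grade accuracy on experimental data.

## Benchmark conditions (dockem.benchmarks)

* **Self-docking recovery**: fixture at R = 3 Å; starting pose fully
  scrambled (uniform orientation, random torsions, translation within
  5 Å); binding-site hint jittered by a 0.5 Å Gaussian; pipeline run
  pre-fitted with 8 replicas × 10 exchange rounds × 200 local moves;
  score = mapped RMSD to the generating pose over 10 seeds.
* **Resolution trend**: the same protocol at R ∈ {3, 8, 12} Å,
  summarized by the median RMSD per resolution.
* **Centering**: site center displaced 4 Å from the true ligand
  centroid; the 500-step centering MC must land the refined c_0 within
  1.5 Å of the truth.

These problem sizes (10 seeds, 8 replicas, 2 × 10 × 200 moves) are the
package's chosen desk-scale conditions; they complete in minutes on one
CPU while leaving the recovery properties clearly resolved.

## Numerical choices and edge cases

* The CC numerator and denominator sums run over one shared voxel index
  set (a Pearson correlation requires matched sets).
* `EnergyModel` caches the local-map lattice and interface pair tables;
  its CC path reproduces the standalone rendering bit-for-bit (verified
  in tests), so reported breakdowns always recompose exactly.
* Local-map extraction keeps every voxel whose center lies within
  edge/2 of the cube center per axis (with a 1e−9 tolerance), clipped
  to the grid; degenerate requests raise geometry errors.
* MRC I/O (via gemmi) normalizes axis permutations to x-fastest order,
  refuses non-orthogonal cells and anisotropic spacing, and stores the
  nominal resolution in a header slot of the extra space (word 49) so
  round-trips preserve it.
* Single-atom "ligands" are rejected where a diameter is required;
  proteins must cover every atom with exactly one residue.
* A replica whose energy turns non-finite is quarantined with a
  diagnostic and the run continues; finite ordering is otherwise
  guaranteed by the clash clamp.

## Known limitations

* Receptor is rigid; no solvation, hydrogen-bond, or entropy terms.
* Protein partial charges default to crude per-element values unless
  the caller overrides them; the Coulomb term's scale is absorbed by
  `w22` rather than being in physical units.
* The isomorphism-based RMSD enumerates automorphisms; molecules with
  enormous symmetry groups (not typical of drug-like ligands) would be
  slow.
* Maps with resolution worse than ~12 Å carry little pose information
  and recovery degrades accordingly — visible in the resolution-trend
  benchmark.
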