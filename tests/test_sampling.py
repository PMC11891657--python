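"""Monte Carlo machinery: ladder, swaps, acceptance, moves, REMC driver."""

import math

import numpy as np
import pytest
from scipy.spatial.distance import pdist

from dockem.errors import MoveUnavailableError, ParameterError
from dockem.sampling import (
    Pose,
    Schedule,
    TorsionTopology,
    metropolis_accept,
    propose_rigid_move,
    propose_torsion_move,
    run_remc,
    swap_probability,
    temperature_ladder,
)


class TestTemperatureLadder:
    def test_endpoints_exact(self):
        t = temperature_ladder(Schedule(N=20, t_min=0.01, t_max=1.0))
        assert t[0] == 0.01
        assert t[-1] == 1.0

    def test_geometric_ratio(self):
        t = temperature_ladder(Schedule(N=20, t_min=0.01, t_max=1.0))
        ratios = t[1:] / t[:-1]
        np.testing.assert_allclose(ratios, ratios[0], atol=1e-12)

    def test_three_replica_midpoint(self):
        t = temperature_ladder(Schedule(N=3, t_min=0.01, t_max=1.0))
        assert t[1] == pytest.approx(0.1, abs=1e-12)

    def test_too_few_replicas(self):
        with pytest.raises(ParameterError):
            Schedule(N=1)


class TestSwapProbability:
    def test_equal_energies(self):
        assert swap_probability(1.7, 1.7, 0.01, 0.5) == 1.0

    def test_equal_temperatures(self):
        assert swap_probability(1.0, 5.0, 0.3, 0.3) == 1.0

    def test_hand_computed_case(self):
        # E_i=1, E_j=3, T_i=0.1, T_j=1, K=1:
        # exponent = (3-1) * (1/1 - 1/0.1) = 2 * (-9) = -18
        assert swap_probability(1.0, 3.0, 0.1, 1.0, K=1.0) == \
            pytest.approx(math.exp(-18.0), rel=1e-12)

    def test_bounds(self):
        rng = np.random.default_rng(0)
        for _ in range(50):
            p = swap_probability(*rng.uniform(0.1, 5.0, size=2),
                                 *rng.uniform(0.01, 1.0, size=2), K=2.0)
            assert 0.0 <= p <= 1.0


class TestMetropolis:
    def test_downhill_always_accepted(self):
        rng = np.random.default_rng(1)
        assert all(metropolis_accept(5.0, 4.9, 0.01, rng) for _ in range(100))

    def test_acceptance_frequency_at_kt(self):
        # dE = K*T: acceptance frequency must approach exp(-1)
        rng = np.random.default_rng(2)
        n = 100_000
        acc = sum(metropolis_accept(0.0, 0.05, 0.05, rng, K=1.0)
                  for _ in range(n))
        assert acc / n == pytest.approx(math.exp(-1), abs=0.01)

    def test_cold_limit_rejects(self):
        rng = np.random.default_rng(3)
        assert not any(metropolis_accept(0.0, 1.0, 1e-9, rng)
                       for _ in range(100))


def chain_pose(lig):
    return Pose.initial(lig)


class TestRigidMoves:
    def test_zero_steps_is_identity(self, butane):
        pose = chain_pose(butane)
        rng = np.random.default_rng(4)
        moved = propose_rigid_move(pose, 0.0, 0.0, rng)
        np.testing.assert_allclose(moved.coords(), pose.coords(), atol=1e-12)

    def test_internal_distances_invariant(self, butane):
        pose = chain_pose(butane)
        rng = np.random.default_rng(5)
        for _ in range(20):
            pose = propose_rigid_move(pose, 2.0, 60.0, rng)
        np.testing.assert_allclose(pdist(pose.coords()),
                                   pdist(butane.coords), atol=1e-9)

    def test_seeded_sequence_reproducible(self, butane):
        def trajectory(seed):
            pose = chain_pose(butane)
            rng = np.random.default_rng(seed)
            out = []
            for _ in range(100):
                pose = propose_rigid_move(pose, 1.0, 30.0, rng)
                out.append(pose.coords())
            return np.array(out)

        np.testing.assert_array_equal(trajectory(7), trajectory(7))
        assert not np.array_equal(trajectory(7), trajectory(8))


class TestTorsionMoves:
    def test_full_turn_is_identity(self, butane):
        pose = chain_pose(butane)
        topo = pose.topology
        a180 = pose.torsions.copy()
        a180[0] = 180.0
        once = topo.apply(butane.coords, a180)
        twice = topo.apply(once, a180)
        np.testing.assert_allclose(twice, butane.coords, atol=1e-9)

    def test_only_distal_fragment_moves(self, butane):
        pose = chain_pose(butane)
        rng = np.random.default_rng(6)
        moved = propose_torsion_move(pose, rng)
        ref = pose.coords()
        new = moved.coords()
        # central bond is 2-3; the distal side is {3, 4} (tie broken toward
        # the second bond atom), and atom 3 sits on the axis
        deltas = np.linalg.norm(new - ref, axis=1)
        assert deltas[0] < 1e-9 and deltas[1] < 1e-9 and deltas[2] < 1e-9
        assert deltas[3] > 1e-3

    def test_bond_lengths_preserved(self, toy_fixture):
        lig = toy_fixture.ligand
        pose = Pose.initial(lig)
        rng = np.random.default_rng(7)
        pos = {a.index: i for i, a in enumerate(lig.atoms)}
        ref_lengths = {
            (b.atom1, b.atom2): np.linalg.norm(
                lig.coords[pos[b.atom1]] - lig.coords[pos[b.atom2]])
            for b in lig.bonds
        }
        for _ in range(25):
            pose = propose_torsion_move(pose, rng)
        new = pose.coords()
        for (a1, a2), d in ref_lengths.items():
            assert np.linalg.norm(new[pos[a1]] - new[pos[a2]]) == \
                pytest.approx(d, abs=1e-9)

    def test_cross_fragment_distances_change(self, butane):
        pose = chain_pose(butane)
        topo = pose.topology
        angles = np.array([90.0])
        new = topo.apply(butane.coords, angles)
        # within the fixed fragment (atoms 1-3) nothing changes
        np.testing.assert_allclose(new[:3], butane.coords[:3], atol=1e-12)
        # across the bond the 1-4 distance must change
        d_old = np.linalg.norm(butane.coords[0] - butane.coords[3])
        d_new = np.linalg.norm(new[0] - new[3])
        assert abs(d_new - d_old) > 0.1

    def test_no_rotatable_bonds_signals(self, benzene):
        pose = Pose.initial(benzene)
        with pytest.raises(MoveUnavailableError):
            propose_torsion_move(pose, np.random.default_rng(8))


class TestPoseInvariants:
    def test_quaternion_normalized(self, butane):
        pose = Pose(translation=(0, 0, 0), quaternion=(2.0, 0, 0, 0),
                    torsions=np.zeros(1), reference_coords=butane.coords,
                    topology=TorsionTopology(butane))
        assert np.linalg.norm(pose.quaternion) == pytest.approx(1.0, abs=1e-12)

    def test_centroid_equals_translation_while_rigid(self, butane):
        rng = np.random.default_rng(9)
        pose = chain_pose(butane)
        for _ in range(5):
            pose = propose_rigid_move(pose, 3.0, 90.0, rng)
            np.testing.assert_allclose(pose.coords().mean(axis=0),
                                       pose.translation, atol=1e-9)

    def test_torsion_moves_leave_anchor_fragment_fixed(self, toy_fixture):
        lig = toy_fixture.ligand
        pose = Pose.initial(lig)
        rng = np.random.default_rng(10)
        moved = propose_torsion_move(pose, rng)
        ref, new = pose.coords(), moved.coords()
        moved_mask = np.linalg.norm(new - ref, axis=1) > 1e-9
        # exactly one distal fragment moved; the anchored majority did not
        assert 0 < moved_mask.sum() < len(lig.atoms) / 2 + 1


def flat_energy(pose):
    return 0.0


def quadratic_energy(target):
    def fn(pose):
        return float(((pose.translation - target) ** 2).sum())
    return fn


class TestRemcDriver:
    def make_poses(self, butane, n):
        return [Pose.initial(butane) for _ in range(n)]

    def test_flat_energy_all_swaps_accepted(self, butane):
        sched = Schedule(N=2, local_steps_per_swap=10, total_sweeps=3)
        result = run_remc(
            self.make_poses(butane, 2), flat_energy, sched,
            lambda p, rng: propose_rigid_move(p, 0.2, 10.0, rng), seed=0)
        assert result.quarantined == []
        assert all(e == 0.0 for tr in result.trace for e in tr)

    def test_swap_preserves_pose_multiset(self, butane):
        # swaps permute poses between slots; with zero-size moves the
        # multiset of coordinates across replicas never changes
        sched = Schedule(N=4, local_steps_per_swap=5, total_sweeps=6)
        poses = []
        for i in range(4):
            p = Pose.initial(butane)
            poses.append(Pose(translation=p.translation + [i, 0, 0],
                              quaternion=p.quaternion, torsions=p.torsions,
                              reference_coords=p.reference_coords,
                              topology=p.topology))
        energies = {i: float(i) for i in range(4)}
        result = run_remc(
            poses, lambda p: float(p.translation[0] - poses[0].translation[0]),
            sched, lambda p, rng: p, seed=1)
        final_x = sorted(round(float(r.pose.translation[0]), 6)
                         for r in result.replicas)
        start_x = sorted(round(float(p.translation[0]), 6) for p in poses)
        assert final_x == start_x

    def test_bit_identical_with_same_seed(self, butane):
        sched = Schedule(N=3, local_steps_per_swap=20, total_sweeps=4)

        def run(seed):
            return run_remc(
                self.make_poses(butane, 3), quadratic_energy(np.ones(3)),
                sched, lambda p, rng: propose_rigid_move(p, 0.5, 20.0, rng),
                seed=seed)

        a, b, c = run(42), run(42), run(43)
        assert a.trace == b.trace
        np.testing.assert_array_equal(a.best_poses[0].coords(),
                                      b.best_poses[0].coords())
        assert a.trace != c.trace

    def test_convergence_on_convex_toy(self, butane):
        target = np.array([5.0, -2.0, 3.0])
        dists = []
        for sweeps in (1, 4, 16):
            sched = Schedule(N=4, local_steps_per_swap=25, total_sweeps=sweeps)
            result = run_remc(
                self.make_poses(butane, 4), quadratic_energy(target), sched,
                lambda p, rng: propose_rigid_move(p, 0.5, 5.0, rng), seed=3)
            best = min(result.best_energies)
            dists.append(math.sqrt(best))
        assert dists[0] >= dists[1] >= dists[2]

    def test_nonfinite_energy_quarantines(self, butane):
        calls = {"n": 0}

        def bad_energy(pose):
            calls["n"] += 1
            return math.inf if calls["n"] > 5 else 0.0

        sched = Schedule(N=2, local_steps_per_swap=10, total_sweeps=2)
        result = run_remc(
            self.make_poses(butane, 2), bad_energy, sched,
            lambda p, rng: propose_rigid_move(p, 0.1, 5.0, rng), seed=4)
        assert result.quarantined  # at least one replica quarantined
        assert any(r.diagnostic for r in result.replicas if not r.active)

    def test_best_energy_is_running_minimum(self, butane):
        sched = Schedule(N=3, local_steps_per_swap=30, total_sweeps=5)
        result = run_remc(
            self.make_poses(butane, 3), quadratic_energy(np.zeros(3)), sched,
            lambda p, rng: propose_rigid_move(p, 0.4, 10.0, rng), seed=5)
        for rep, tr in zip(result.replicas, result.trace):
            assert float(rep.best_energy) <= min(tr) + 1e-12
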