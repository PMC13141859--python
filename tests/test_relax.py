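import numpy as np
import pytest

from ternscan import (
    Atom,
    RestraintStage,
    SoftSphereParams,
    Structure,
    Trajectory,
    build_restraint_schedule,
    concat,
    equilibration_filter,
    make_toy_protein,
    restrained_minimize,
    select_representative,
)
from ternscan.relax import _energy_and_gradient


def _protein_ligand_roster():
    protein = make_toy_protein(4, sidechain_atoms=2, seed=0)
    ligand = Structure(
        [Atom("C", f"L{i}", 1, "LIG", "L", (30.0 + i * 3, 0.0, 0.0)) for i in range(4)]
    )
    return concat([protein, ligand])


class TestRestraintSchedule:
    def test_four_stages_with_force_constant_10(self):
        schedule = build_restraint_schedule()
        assert len(schedule.stages) == 4
        assert all(s.force_constant == 10.0 for s in schedule.stages)
        assert all(s.action == "minimize" for s in schedule.stages)

    def test_release_order_sidechains_backbone_ligand(self):
        roster = _protein_ligand_roster()
        schedule = build_restraint_schedule()
        masks = [stage.restrained_mask(roster) for stage in schedule.stages]
        schedule.validate_monotone(roster)
        # stage 1 holds every heavy atom
        np.testing.assert_array_equal(masks[0], roster.is_heavy)
        # stage 2 frees exactly the protein sidechains
        freed_2 = masks[0] & ~masks[1]
        assert set(roster.names[freed_2]) == {"SC1", "SC2"}
        # stage 3 frees the protein backbone, keeping only the ligand held
        freed_3 = masks[1] & ~masks[2]
        assert set(roster.names[freed_3]) == {"N", "CA", "C", "O"}
        assert set(roster.residue_names[masks[2]]) == {"LIG"}
        # stage 4 restrains nothing
        assert masks[3].sum() == 0

    def test_monotone_violation_detected(self):
        roster = _protein_ligand_roster()
        from ternscan import RestraintSchedule

        bad = RestraintSchedule(
            stages=(
                RestraintStage("only-ligand", "ligand"),
                RestraintStage("regrab-everything", "heavy"),
            )
        )
        with pytest.raises(ValueError, match="re-restrains"):
            bad.validate_monotone(roster)

    def test_negative_force_constant_rejected(self):
        with pytest.raises(ValueError):
            RestraintStage("bad", "heavy", force_constant=-1.0)


class TestEquilibrationFilter:
    def _trajectory(self, times):
        base = make_toy_protein(2, seed=1)
        frames = [base.with_coords(base.coords + i * 0.01) for i in range(len(times))]
        return Trajectory(frames=frames, times_ns=np.asarray(times, dtype=float))

    def test_paper_cadence_50ns_half_ns_discard_10_keeps_80(self):
        traj = self._trajectory(np.arange(1, 101) * 0.5)  # 0.5 .. 50 ns
        kept = equilibration_filter(traj, discard_ns=10.0)
        assert len(kept) == 80
        assert kept.times_ns[0] == 10.5

    def test_discard_zero_is_identity(self):
        traj = self._trajectory([0.5, 1.0, 1.5])
        kept = equilibration_filter(traj, discard_ns=0.0)
        assert len(kept) == 3

    def test_all_discarded_warns_and_returns_empty(self):
        traj = self._trajectory([5.0])
        with pytest.warns(UserWarning, match="discarded every frame"):
            kept = equilibration_filter(traj, discard_ns=10.0)
        assert len(kept) == 0

    def test_idempotent(self):
        traj = self._trajectory(np.arange(1, 41) * 0.5)
        once = equilibration_filter(traj, discard_ns=7.0)
        twice = equilibration_filter(once, discard_ns=7.0)
        assert len(once) == len(twice)
        np.testing.assert_array_equal(once.times_ns, twice.times_ns)

    def test_non_increasing_times_rejected(self):
        with pytest.raises(ValueError):
            self._trajectory([1.0, 1.0, 2.0])


def _brute_force_medoid(frames, align_idx, rmsd_idx):
    """Independent all-pairs oracle using a from-scratch SVD superposition."""
    n = len(frames)
    medians = []
    for i in range(n):
        ref_a = frames[i].coords[align_idx]
        ref_r = frames[i].coords[rmsd_idx]
        vals = []
        for j in range(n):
            if j == i:
                continue
            mob_a = frames[j].coords[align_idx]
            mc, rc = mob_a.mean(0), ref_a.mean(0)
            H = (mob_a - mc).T @ (ref_a - rc)
            U, _, Vt = np.linalg.svd(H)
            d = np.sign(np.linalg.det(Vt.T @ U.T))
            R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
            moved = (frames[j].coords[rmsd_idx] - mc) @ R.T + rc
            vals.append(np.sqrt(np.mean(np.sum((moved - ref_r) ** 2, axis=1))))
        medians.append(np.median(vals))
    return int(np.argmin(medians)), medians


class TestSelectRepresentative:
    def _frames(self, rng, n_frames, scales=None):
        base = make_toy_protein(4, sidechain_atoms=1, seed=3)
        scales = scales if scales is not None else rng.uniform(0.3, 1.5, size=n_frames)
        frames = [
            base.with_coords(base.coords + rng.normal(0, s, size=base.coords.shape))
            for s in scales
        ]
        return frames

    def test_single_frame_returns_zero(self):
        base = make_toy_protein(2, seed=4)
        traj = Trajectory(frames=[base], times_ns=[1.0])
        assert select_representative(traj, "backbone", "calpha") == 0

    def test_identical_frames_tie_break_to_lowest_index(self):
        base = make_toy_protein(2, seed=5)
        traj = Trajectory(frames=[base] * 4, times_ns=[1.0, 2.0, 3.0, 4.0])
        assert select_representative(traj, "backbone", "calpha") == 0

    @pytest.mark.parametrize("n_frames,seed", [(5, 0), (9, 1), (14, 2), (20, 3)])
    def test_agrees_with_exhaustive_all_pairs_oracle(self, n_frames, seed):
        rng = np.random.default_rng(seed)
        frames = self._frames(rng, n_frames)
        traj = Trajectory(frames=frames, times_ns=np.arange(1, n_frames + 1, dtype=float))
        align_idx = np.flatnonzero(frames[0].is_backbone)
        rmsd_idx = np.flatnonzero(frames[0].is_calpha)
        expected, _ = _brute_force_medoid(frames, align_idx, rmsd_idx)
        assert select_representative(traj, "backbone", "calpha") == expected

    def test_planted_medoid_wins(self):
        rng = np.random.default_rng(17)
        # frame 3 perturbed far less than the rest -> it is the medoid
        scales = [2.0, 2.0, 2.0, 0.05, 2.0, 2.0]
        frames = self._frames(rng, 6, scales=scales)
        traj = Trajectory(frames=frames, times_ns=np.arange(1.0, 7.0))
        assert select_representative(traj, "backbone", "calpha") == 3

    def test_choice_stable_under_frame_reordering(self):
        rng = np.random.default_rng(18)
        frames = self._frames(rng, 7)
        traj = Trajectory(frames=frames, times_ns=np.arange(1.0, 8.0))
        chosen = select_representative(traj, "backbone", "calpha")
        order = list(rng.permutation(7))
        shuffled = Trajectory(
            frames=[frames[i] for i in order], times_ns=np.arange(1.0, 8.0)
        )
        chosen_shuffled = select_representative(shuffled, "backbone", "calpha")
        assert order[chosen_shuffled] == chosen

    def test_empty_selection_rejected(self):
        base = make_toy_protein(2, seed=6)
        traj = Trajectory(frames=[base, base], times_ns=[1.0, 2.0])
        with pytest.raises(ValueError, match="selection"):
            select_representative(traj, "resname XYZ", "calpha")


class TestRestrainedMinimize:
    def _two_atoms(self, separation):
        return Structure(
            [
                Atom("C", "X1", 1, "UNK", "A", (0.0, 0.0, 0.0)),
                Atom("C", "X2", 2, "UNK", "A", (separation, 0.0, 0.0)),
            ]
        )

    def test_overlapping_free_atoms_separate(self):
        start = self._two_atoms(1.0)
        stage = RestraintStage("free", "", force_constant=0.0)
        relaxed = restrained_minimize(start, start, stage, max_steps=300)
        d0 = 1.0
        d1 = np.linalg.norm(relaxed.coords[1] - relaxed.coords[0])
        assert d1 > d0

    def test_restrained_atom_returns_to_reference(self):
        reference = Structure([Atom("C", "X1", 1, "UNK", "A", (0.0, 0.0, 0.0))])
        displaced = reference.with_coords(np.array([[1.0, 0.0, 0.0]]))
        stage = RestraintStage("hold", "all")
        relaxed = restrained_minimize(displaced, reference, stage, max_steps=2000, tol=1e-6)
        assert np.linalg.norm(relaxed.coords[0]) < 0.01

    def test_unrestrained_atom_moves_farther_than_restrained(self):
        start = Structure(
            [
                Atom("C", "HELD", 1, "UNK", "A", (0.0, 0.0, 0.0)),
                Atom("C", "FREE", 2, "UNK", "A", (1.2, 0.0, 0.0)),
            ]
        )
        stage = RestraintStage("partial", "name HELD", force_constant=10.0)
        relaxed = restrained_minimize(start, start, stage, max_steps=400)
        moved = np.linalg.norm(relaxed.coords - start.coords, axis=1)
        assert moved[1] > moved[0]

    def test_energy_never_increases_along_descent(self):
        rng = np.random.default_rng(19)
        coords = rng.uniform(0, 4, size=(8, 3))
        structure = Structure(
            [Atom("C", f"X{i}", i + 1, "UNK", "A", coords[i]) for i in range(8)]
        )
        stage = RestraintStage("hold-all", "all", force_constant=2.0)
        potential = SoftSphereParams()
        restrained = stage.restrained_mask(structure)
        e_start, _ = _energy_and_gradient(
            structure.coords, structure.coords, restrained, stage.force_constant, potential
        )
        relaxed = restrained_minimize(structure, structure, stage, potential, max_steps=50)
        e_end, _ = _energy_and_gradient(
            relaxed.coords, structure.coords, restrained, stage.force_constant, potential
        )
        assert e_end <= e_start + 1e-12

    def test_roster_mismatch_rejected(self):
        a = self._two_atoms(3.0)
        b = make_toy_protein(1, seed=7)
        with pytest.raises(ValueError, match="roster"):
            restrained_minimize(a, b, RestraintStage("s", "all"))
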