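"""Hydrogen-bond geometry, occupancy counting, and composite semantics."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from mdcompare import (HBondCriteria, HBondTriple, Topology, Trajectory,
                       composite_occupancy, find_donors_acceptors,
                       hbond_present, occupancy, select)
from mdcompare.errors import GeometryError, MDCompareError
from mdcompare.synthetic import (GeneratorSpec, gen_hbond_trajectory,
                                 iid_rates)


def _all(topology):
    return select(topology, "chain A or chain B")


class TestDonorsAcceptors:
    def test_toy_complex_donors_are_exactly_the_nh_pairs(self, toy_complex):
        topology, _ = toy_complex
        donors, acceptors = find_donors_acceptors(topology, _all(topology))
        # one N-H donor per residue; acceptors are every N and O
        n_res = len(list(topology.residues()))
        assert len(donors) == n_res
        assert all(topology.names[d] == "N" and topology.names[h] == "H"
                   for d, h in donors)
        assert len(acceptors) == 2 * n_res
        assert {topology.names[a] for a in acceptors} == {"N", "O"}

    def test_multiple_hydrogens_give_multiple_donor_entries(self):
        # lysine-like amine: one N with three protons -> three donor entries
        topology = Topology(
            ["NZ", "HZ1", "HZ2", "HZ3", "C", "O"],
            ["N", "H", "H", "H", "C", "O"],
            ["LYS"] * 4 + ["GLY"] * 2, [1] * 4 + [2] * 2, ["A"] * 6,
            bonds=[(0, 1), (0, 2), (0, 3), (4, 5)])
        donors, acceptors = find_donors_acceptors(
            topology, select(topology, "chain A"))
        assert [d for d, _h in donors] == [0, 0, 0]
        assert set(acceptors) == {0, 5}  # carbonyl O is acceptor only

    def test_no_polar_atoms_warns_and_returns_empty(self, caplog):
        topology = Topology(["C1", "H1"], ["C", "H"], ["UNK"] * 2, [1, 1],
                            ["A"] * 2, bonds=[(0, 1)])
        with caplog.at_level("WARNING"):
            donors, acceptors = find_donors_acceptors(
                topology, select(topology, "chain A"))
        assert donors == [] and acceptors == []
        assert "no N/O" in caplog.text

    def test_structures_without_hydrogens_rejected(self):
        topology = Topology(["N", "O"], ["N", "O"], ["UNK"] * 2, [1, 1],
                            ["A"] * 2)
        with pytest.raises(MDCompareError, match="hydrogen"):
            find_donors_acceptors(topology, select(topology, "chain A"))


def _frame(da_distance, dha_angle_deg):
    """Donor at origin, H on +x; acceptor placed at the requested geometry."""
    theta = np.radians(180.0 - dha_angle_deg)
    h = np.array([1.0, 0.0, 0.0])
    direction = np.array([np.cos(theta), np.sin(theta), 0.0])
    # position acceptor so the D-A distance is exact
    lo, hi = 0.0, 20.0
    for _ in range(80):  # bisect on the distance along the angular ray
        mid = 0.5 * (lo + hi)
        a = h + mid * direction
        if np.linalg.norm(a) < da_distance:
            lo = mid
        else:
            hi = mid
    a = h + 0.5 * (lo + hi) * direction
    return np.array([[0.0, 0.0, 0.0], h, a])


class TestPerFrameGeometry:
    TRIPLE = HBondTriple(donor=0, hydrogen=1, acceptor=2)

    @pytest.mark.parametrize("distance, angle, expected", [
        (2.9, 170.0, True),
        (3.01, 170.0, False),    # distance just outside
        (2.9, 134.9, False),     # angle just outside
    ])
    def test_cutoff_boundaries(self, distance, angle, expected):
        frame = _frame(distance, angle)
        assert hbond_present(frame, self.TRIPLE, HBondCriteria()) is expected

    def test_exact_distance_boundary_counts_bonded(self):
        # collinear geometry: D-A exactly at the cutoff, angle 180
        frame = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [3.0, 0.0, 0.0]])
        assert hbond_present(frame, self.TRIPLE, HBondCriteria()) is True

    def test_coincident_donor_acceptor_is_geometry_error(self):
        frame = np.array([[0.0, 0.0, 0.0], [1.0, 0.0, 0.0], [0.0, 0.0, 0.0]])
        with pytest.raises(GeometryError):
            hbond_present(frame, self.TRIPLE, HBondCriteria())


class TestOccupancy:
    def test_always_and_never_bonded(self):
        spec_on = GeneratorSpec(seed=3, n_frames=200, hbond_rates=((0.5, 0.0),))
        sc = gen_hbond_trajectory(spec_on)
        (rec,) = occupancy(sc.trajectory, sc.triples)
        assert rec.occupancy == 100.0 and rec.n_bonded_frames == 200

        spec_off = GeneratorSpec(seed=3, n_frames=200, hbond_rates=((0.0, 0.5),))
        sc = gen_hbond_trajectory(spec_off)
        (rec,) = occupancy(sc.trajectory, sc.triples)
        assert rec.occupancy == 0.0
        assert rec.low

    def test_occupancy_equals_hidden_state_count_exactly(self):
        sc = gen_hbond_trajectory(GeneratorSpec(seed=11, n_frames=3000))
        (rec,) = occupancy(sc.trajectory, sc.triples)
        assert rec.n_bonded_frames == int(sc.states[:, 0].sum())
        assert rec.occupancy == 100.0 * rec.n_bonded_frames / rec.n_frames

    def test_estimator_error_shrinks_with_frame_count(self):
        # stationary bonded fraction is 0.70; average error over seeds
        # must drop from 1k to 10k frames
        def mean_error(n_frames):
            errs = []
            for seed in range(5):
                sc = gen_hbond_trajectory(GeneratorSpec(seed=seed,
                                                        n_frames=n_frames))
                (rec,) = occupancy(sc.trajectory, sc.triples)
                errs.append(abs(rec.occupancy - 70.0))
            return np.mean(errs)

        assert mean_error(10_000) < mean_error(1_000)

    def test_rigid_transform_invariance(self):
        sc = gen_hbond_trajectory(GeneratorSpec(seed=5, n_frames=400))
        (before,) = occupancy(sc.trajectory, sc.triples)
        theta = 0.7
        rot = np.array([[np.cos(theta), -np.sin(theta), 0],
                        [np.sin(theta), np.cos(theta), 0], [0, 0, 1.0]])
        moved = Trajectory(sc.trajectory.topology,
                           sc.trajectory.coords @ rot.T + [10.0, -3.0, 2.0])
        (after,) = occupancy(moved, sc.triples)
        assert after.n_bonded_frames == before.n_bonded_frames

    def test_threshold_monotonicity(self):
        sc = gen_hbond_trajectory(GeneratorSpec(seed=9, n_frames=500))
        tight = occupancy(sc.trajectory, sc.triples,
                          HBondCriteria(2.95, 160.0))[0].occupancy
        default = occupancy(sc.trajectory, sc.triples,
                            HBondCriteria(3.0, 135.0))[0].occupancy
        loose = occupancy(sc.trajectory, sc.triples,
                          HBondCriteria(4.0, 100.0))[0].occupancy
        assert tight <= default <= loose

    def test_empty_triple_list(self, toy_complex):
        topology, base = toy_complex
        assert occupancy(Trajectory(topology, base), []) == []

    def test_triple_validation(self, toy_complex):
        topology, base = toy_complex
        traj = Trajectory(topology, base)
        with pytest.raises(MDCompareError, match="bonded"):
            occupancy(traj, [HBondTriple(donor=0, hydrogen=4, acceptor=9)])


class TestCompositeOccupancy:
    def test_sum_and_union_against_hidden_states(self):
        spec = GeneratorSpec(seed=21, n_frames=4000,
                             hbond_rates=(iid_rates(0.4), iid_rates(0.2)))
        sc = gen_hbond_trajectory(spec)
        total = composite_occupancy(sc.trajectory, sc.triples, mode="sum")
        union = composite_occupancy(sc.trajectory, sc.triples, mode="union")
        assert total == pytest.approx(100.0 * sc.states.mean(axis=0).sum())
        assert union == pytest.approx(100.0 * sc.states.any(axis=1).mean())
        # independent duty cycles 0.4 and 0.2: union -> 1 - 0.6*0.8 = 0.52
        assert union == pytest.approx(52.0, abs=3.0)
        assert total == pytest.approx(60.0, abs=3.0)

    def test_modes_on_saturated_bonds(self):
        spec = GeneratorSpec(seed=2, n_frames=100,
                             hbond_rates=((0.5, 0.0), (0.5, 0.0)))
        sc = gen_hbond_trajectory(spec)
        assert composite_occupancy(sc.trajectory, sc.triples, mode="sum") == 200.0
        assert composite_occupancy(sc.trajectory, sc.triples, mode="union") == 100.0

    def test_unknown_mode_and_empty_group(self, toy_complex):
        topology, base = toy_complex
        traj = Trajectory(topology, base)
        with pytest.raises(MDCompareError, match="mode"):
            composite_occupancy(traj, [HBondTriple(0, 1, 9)], mode="mean")
        with pytest.raises(MDCompareError, match="non-empty"):
            composite_occupancy(traj, [], mode="sum")

    @settings(max_examples=25, derandomize=True, deadline=None)
    @given(duty=st.tuples(st.floats(0.05, 0.95), st.floats(0.05, 0.95)),
           seed=st.integers(0, 50))
    def test_union_never_exceeds_min_of_100_and_sum(self, duty, seed):
        spec = GeneratorSpec(seed=seed, n_frames=300,
                             hbond_rates=tuple(iid_rates(d) for d in duty))
        sc = gen_hbond_trajectory(spec)
        total = composite_occupancy(sc.trajectory, sc.triples, mode="sum")
        union = composite_occupancy(sc.trajectory, sc.triples, mode="union")
        assert union <= min(100.0, total) + 1e-9
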