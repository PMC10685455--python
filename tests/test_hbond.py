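"""IMHB detection, reweighted occupancy, donor shares, phase comparison."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from macrorew.core_io import Atom, Topology, Trajectory
from macrorew.hbond import (
    ContactMap,
    HBondCriteria,
    compare_phases,
    contact_occupancy,
    detect_frame,
    donor_contributions,
    find_donors_acceptors,
    ring_distance,
)
from macrorew.synthgen import plant_hbond_trajectory, toy_macrocycle


def _brute_force_contacts(coords, donors, acceptors, criteria, sep):
    """Independent triple loop over (donor, H, acceptor)."""
    out = set()
    for d in donors:
        for a in acceptors:
            if a == d.heavy:
                continue
            if sep[d.heavy, a] < criteria.min_separation:
                continue
            if np.linalg.norm(coords[d.heavy] - coords[a]) > criteria.d_max:
                continue
            v1 = coords[d.heavy] - coords[d.hydrogen]
            v2 = coords[a] - coords[d.hydrogen]
            cosang = v1 @ v2 / (np.linalg.norm(v1) * np.linalg.norm(v2))
            ang = np.degrees(np.arccos(np.clip(cosang, -1, 1)))
            if ang >= criteria.angle_min:
                out.add((d.heavy, a))
    return out


class TestDonorsAcceptors:
    def test_n_methylacetamide(self, nma_topology):
        donors, acceptors = find_donors_acceptors(nma_topology)
        assert [(d.heavy, d.hydrogen) for d in donors] == [(6, 7)]
        assert acceptors == [5]  # carbonyl O only; amide N excluded

    def test_fully_n_methylated_amide(self, nma_topology):
        # replace the N-H with an N-methyl: no donors remain, O still accepts
        atoms = list(nma_topology.atoms)
        atoms[7] = Atom(7, "C4", "C", 0, "NMA")
        topo = Topology(atoms=atoms, bonds=list(nma_topology.bonds))
        donors, acceptors = find_donors_acceptors(topo)
        assert donors == []
        assert acceptors == [5]

    def test_no_hydrogens_is_an_error(self):
        atoms = [Atom(0, "N", "N", 0, "X"), Atom(1, "C", "C", 0, "X")]
        topo = Topology(atoms=atoms, bonds=[(0, 1)])
        with pytest.raises(ValueError, match="explicit H"):
            find_donors_acceptors(topo)

    def test_toy_macrocycle_counts(self, macrocycle):
        topo, _ = macrocycle
        donors, acceptors = find_donors_acceptors(topo)
        assert len(donors) == 4  # 3 amide N-H + 1 secondary amine N-H
        assert len(acceptors) == 3  # the 3 carbonyl oxygens
        assert all(topo.atoms[a].element == "O" for a in acceptors)


def _linear_probe(n_o_distance, angle_at_h):
    """N-H···O probe with adjustable geometry; N and O are 3 bonds apart."""
    atoms = [
        Atom(0, "N", "N", 0, "X"),
        Atom(1, "H", "H", 0, "X"),
        Atom(2, "C1", "C", 0, "X"),
        Atom(3, "C2", "C", 0, "X"),
        Atom(4, "O", "O", 0, "X"),
    ]
    bonds = [(0, 1), (0, 2), (2, 3), (3, 4)]
    topo = Topology(atoms=atoms, bonds=bonds)
    h = np.array([1.0, 0.0, 0.0])
    # place O so that |N-O| = n_o_distance and the N-H···O angle is angle_at_h
    theta = np.radians(angle_at_h)
    t = np.cos(theta) + np.sqrt(np.cos(theta) ** 2 - 1 + n_o_distance**2)
    o = h + t * np.array([-np.cos(theta), np.sin(theta), 0.0])
    coords = np.array([[0, 0, 0], h, [10, 10, 0], [10, 11, 0], o], dtype=float)
    return topo, coords


class TestDetect:
    def test_ideal_linear_geometry(self):
        topo, coords = _linear_probe(2.9, 180.0)
        donors, acceptors = find_donors_acceptors(topo)
        got = detect_frame(coords, donors, acceptors, HBondCriteria(), topo)
        assert got == {(0, 4)}

    def test_beyond_distance_cutoff(self):
        topo, coords = _linear_probe(3.6, 180.0)
        donors, acceptors = find_donors_acceptors(topo)
        assert detect_frame(coords, donors, acceptors, HBondCriteria(), topo) == set()

    def test_distance_cutoff_inclusive(self):
        topo, coords = _linear_probe(3.5, 180.0)
        donors, acceptors = find_donors_acceptors(topo)
        assert detect_frame(coords, donors, acceptors, HBondCriteria(), topo) == {(0, 4)}

    @pytest.mark.parametrize("angle,expect", [(89.9, set()), (90.0, {(0, 4)})])
    def test_angle_boundary_inclusive(self, angle, expect):
        topo, coords = _linear_probe(2.9, angle)
        donors, acceptors = find_donors_acceptors(topo)
        assert detect_frame(coords, donors, acceptors, HBondCriteria(), topo) == expect

    def test_min_separation_excludes_adjacent(self):
        topo, coords = _linear_probe(2.9, 180.0)
        donors, acceptors = find_donors_acceptors(topo)
        crit = HBondCriteria(min_separation=4)
        assert detect_frame(coords, donors, acceptors, crit, topo) == set()

    def test_equals_brute_force_on_random_frames(self, macrocycle, rng):
        topo, base = macrocycle
        donors, acceptors = find_donors_acceptors(topo)
        crit = HBondCriteria()
        sep = topo.bond_separation_matrix()
        for _ in range(100):
            coords = base + rng.normal(0, 1.2, size=base.shape)
            got = detect_frame(coords, donors, acceptors, crit, topo, sep)
            want = _brute_force_contacts(coords, donors, acceptors, crit, sep)
            assert got == want


class TestOccupancy:
    def test_always_formed_gives_one(self, macrocycle, rng):
        topo, base = macrocycle
        w = rng.random(50)
        w /= w.sum()
        traj, achieved = plant_hbond_trajectory(topo, base, {(3, 15): 1.0}, 50, weights=w)
        donors, acceptors = find_donors_acceptors(topo)
        cmap = contact_occupancy(traj, w, HBondCriteria(), donors, acceptors)
        assert cmap.occupancy[1, 1] == pytest.approx(1.0, abs=1e-12)

    def test_half_formed_uniform(self, macrocycle):
        topo, base = macrocycle
        traj, achieved = plant_hbond_trajectory(topo, base, {(3, 15): 0.5}, 40)
        donors, acceptors = find_donors_acceptors(topo)
        w = np.full(40, 1 / 40)
        cmap = contact_occupancy(traj, w, HBondCriteria(), donors, acceptors)
        assert cmap.occupancy[1, 1] == pytest.approx(0.5, abs=1e-12)
        assert achieved[(3, 15)] == pytest.approx(0.5, abs=1e-12)

    def test_planted_occupancy_recovered_exactly(self, macrocycle, rng):
        from conftest import dyadic_weights

        topo, base = macrocycle
        w = dyadic_weights(rng, 300)
        traj, achieved = plant_hbond_trajectory(
            topo, base, {(3, 15): 0.37}, 300, weights=w, seed=2
        )
        donors, acceptors = find_donors_acceptors(topo)
        cmap = contact_occupancy(traj, w, HBondCriteria(), donors, acceptors)
        assert cmap.occupancy[1, 1] == achieved[(3, 15)]
        assert achieved[(3, 15)] == pytest.approx(0.37, abs=0.01)

    def test_rigid_motion_invariance(self, macrocycle, rng):
        from scipy.spatial.transform import Rotation

        topo, base = macrocycle
        traj, _ = plant_hbond_trajectory(topo, base, {(3, 15): 0.4}, 30)
        w = np.full(30, 1 / 30)
        donors, acceptors = find_donors_acceptors(topo)
        crit = HBondCriteria()
        cmap = contact_occupancy(traj, w, crit, donors, acceptors)
        rot = Rotation.random(30, random_state=5).as_matrix()
        moved = np.einsum("fij,faj->fai", rot, traj.coords) + rng.normal(0, 10, (30, 1, 3))
        cmap2 = contact_occupancy(
            Trajectory(moved, topo, 1.0), w, crit, donors, acceptors
        )
        np.testing.assert_allclose(cmap2.occupancy, cmap.occupancy, atol=1e-9)

    def test_split_and_recombine(self, macrocycle, rng):
        topo, base = macrocycle
        n = 60
        w = rng.random(n)
        w /= w.sum()
        traj, _ = plant_hbond_trajectory(topo, base, {(3, 15): 0.4}, n, weights=w, seed=1)
        donors, acceptors = find_donors_acceptors(topo)
        crit = HBondCriteria()
        full = contact_occupancy(traj, w, crit, donors, acceptors)
        mid = n // 2
        parts = []
        for sl in (slice(0, mid), slice(mid, n)):
            wh = w[sl] / w[sl].sum()
            half = Trajectory(traj.coords[sl], topo, 1.0)
            parts.append((w[sl].sum(), contact_occupancy(half, wh, crit, donors, acceptors)))
        mixed = sum(frac * cm.occupancy for frac, cm in parts)
        np.testing.assert_allclose(mixed, full.occupancy, atol=1e-12)


class TestContributions:
    def test_single_cell(self):
        cmap = ContactMap(["D1", "D2"], ["A1"], np.array([[0.8], [0.0]]))
        np.testing.assert_allclose(donor_contributions(cmap), [100.0, 0.0])

    def test_row_sums(self):
        cmap = ContactMap(["D1", "D2"], ["A1", "A2"],
                          np.array([[0.2, 0.1], [0.05, 0.05]]))
        np.testing.assert_allclose(donor_contributions(cmap), [75.0, 25.0])

    def test_all_zero_is_undefined(self):
        cmap = ContactMap(["D1"], ["A1"], np.zeros((1, 1)))
        assert np.isnan(donor_contributions(cmap)).all()

    @given(st.integers(0, 2**31 - 1))
    @settings(max_examples=20, deadline=None, derandomize=True)
    def test_shares_sum_to_100(self, seed):
        occ = np.random.default_rng(seed).random((4, 3)) * 0.3
        cmap = ContactMap([f"D{i}" for i in range(4)], [f"A{j}" for j in range(3)], occ)
        shares = donor_contributions(cmap)
        assert shares.sum() == pytest.approx(100.0, abs=1e-9)
        # independent hand summation
        np.testing.assert_allclose(
            shares, occ.sum(axis=1) / occ.sum() * 100.0, atol=1e-12
        )


class TestPhaseComparison:
    def test_identical_maps_zero_difference(self, macrocycle, rng):
        topo, _ = macrocycle
        donors, acceptors = find_donors_acceptors(topo)
        occ = rng.random((len(donors), len(acceptors))) * 0.5
        cmap = ContactMap([d.label for d in donors], ["A1", "A2", "A3"], occ)
        cmp = compare_phases(cmap, cmap, topo, donors, acceptors)
        np.testing.assert_allclose(cmp.difference, 0.0)
        assert cmp.short_range_total == 0.0 and cmp.long_range_total == 0.0

    def test_ring_distance_classification(self):
        # 4-residue ring: adjacent pair short-range, opposite pair long-range
        assert ring_distance(0, 1, 4) == 1
        assert ring_distance(0, 3, 4) == 1  # wraps around the ring
        assert ring_distance(0, 2, 4) == 2

    def test_difference_is_elementwise(self, macrocycle, rng):
        topo, _ = macrocycle
        donors, acceptors = find_donors_acceptors(topo)
        a = rng.random((len(donors), len(acceptors))) * 0.5
        b = rng.random((len(donors), len(acceptors))) * 0.5
        labels = ([d.label for d in donors], ["A1", "A2", "A3"])
        cmp = compare_phases(
            ContactMap(labels[0], labels[1], a),
            ContactMap(labels[0], labels[1], b),
            topo, donors, acceptors,
        )
        np.testing.assert_allclose(cmp.difference, b - a, atol=1e-15)
        np.testing.assert_allclose(cmp.per_donor_difference, (b - a).sum(axis=1), atol=1e-14)
        assert cmp.short_range_total + cmp.long_range_total == pytest.approx(
            (b - a).sum(), abs=1e-12
        )

    def test_label_mismatch_is_structural_error(self, macrocycle):
        topo, _ = macrocycle
        donors, acceptors = find_donors_acceptors(topo)
        a = ContactMap(["D1"], ["A1"], np.zeros((1, 1)))
        b = ContactMap(["Dx"], ["A1"], np.zeros((1, 1)))
        with pytest.raises(ValueError, match="mismatch"):
            compare_phases(a, b, topo, donors, acceptors)
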