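"""Rigid-body Monte Carlo docking and interface statistics."""

import numpy as np
import pytest

from gofold import mced
from gofold.mced import (
    DimerEnsemble,
    DimerPose,
    InterfaceStatistics,
    MCParams,
    cation_pi_candidates,
    contact_probability_map,
    density_histogram,
    dock_pair,
    docking_axis,
    ensemble_dock,
    hotspot_profile,
    interaction_partners,
    intermolecular_contacts,
    top_contacts,
)
from gofold.structure_io import AtomRecord, ProteinStructure, assign_radii


def single_atom_monomer(x, residue=1, name="CB", resname="ALA"):
    return assign_radii(
        ProteinStructure(
            [AtomRecord(1, name, "C", residue, resname, [x, 0.0, 0.0])]
        )
    )


def blob(n_res, seed, spread=3.0, first_residue=1, resnames=None):
    """Compact random cluster of single-atom residues, clash-free."""
    rng = np.random.default_rng(seed)
    coords = []
    while len(coords) < n_res:
        c = rng.uniform(-spread, spread, 3)
        if all(np.linalg.norm(c - p) > 3.2 for p in coords):
            coords.append(c)
    atoms = [
        AtomRecord(k + 1, "CB", "C", first_residue + k,
                   (resnames or ["ALA"] * n_res)[k], c)
        for k, c in enumerate(coords)
    ]
    return assign_radii(ProteinStructure(atoms))


class TestDockingAxis:
    def test_axis_is_normalized_center_difference(self):
        a = single_atom_monomer(0.0)
        b = single_atom_monomer(10.0)
        axis, t0 = docking_axis(a, b)
        np.testing.assert_allclose(axis, [1.0, 0, 0])

    def test_initial_placement_beyond_contact_range(self):
        a = blob(5, 1)
        b = blob(5, 2)
        b = b.with_coords(b.coords + np.array([15.0, 0, 0]))
        axis, t0 = docking_axis(a, b)
        contacts, clashes = intermolecular_contacts(
            a, b, np.eye(3), t0
        )
        assert len(contacts) == 0 and clashes == 0

    def test_world_rotation_covariance(self):
        from scipy.spatial.transform import Rotation

        a = blob(5, 1)
        b = blob(5, 2)
        b = b.with_coords(b.coords + np.array([15.0, 2.0, -3.0]))
        axis, _ = docking_axis(a, b)
        R = Rotation.from_rotvec([0.3, -0.2, 0.5]).as_matrix()
        a2 = a.with_coords(a.coords @ R.T)
        b2 = b.with_coords(b.coords @ R.T)
        axis2, _ = docking_axis(a2, b2)
        np.testing.assert_allclose(axis2, R @ axis, atol=1e-9)

    def test_coincident_centers_rejected(self):
        a = single_atom_monomer(0.0)
        with pytest.raises(ValueError, match="coincident"):
            docking_axis(a, a)


class TestIntermolecularContacts:
    def test_single_pair_in_well(self):
        # sigma = 2.944, well edge 4.7104 for two 1.84 A carbons
        a = single_atom_monomer(0.0)
        b = single_atom_monomer(1.1 * 2.944)
        contacts, clashes = intermolecular_contacts(a, b)
        assert contacts == frozenset({(1, 1)}) and clashes == 0

    def test_single_pair_clash(self):
        a = single_atom_monomer(0.0)
        b = single_atom_monomer(0.9 * 2.944)
        contacts, clashes = intermolecular_contacts(a, b)
        assert len(contacts) == 0 and clashes == 1

    def test_matches_brute_force_oracle(self):
        a = blob(8, 3)
        b = blob(6, 4)
        rng = np.random.default_rng(5)
        for _ in range(10):
            t = rng.uniform(-8, 8, 3)
            contacts, clashes = intermolecular_contacts(a, b, None, t)
            # O(N^2) re-derivation
            exp_contacts, exp_clashes = set(), 0
            for i, ai in enumerate(a.atoms):
                for j, bj in enumerate(b.atoms):
                    d = np.linalg.norm(
                        ai.coordinates - (bj.coordinates + t)
                    )
                    sigma = 0.8 * (ai.vdw_radius + bj.vdw_radius)
                    if d < sigma:
                        exp_clashes += 1
                    elif d <= 1.6 * sigma:
                        exp_contacts.add(
                            (ai.residue_number, bj.residue_number)
                        )
            assert contacts == frozenset(exp_contacts)
            assert clashes == exp_clashes

    def test_pose_self_consistency(self, lock_key):
        pose = dock_pair(
            lock_key.body_a, lock_key.body_b,
            MCParams(n_steps=2000, n_restarts=2), seed=0,
        )
        again, cl = intermolecular_contacts(
            lock_key.body_a, lock_key.body_b,
            pose.rotation, pose.translation,
        )
        assert again == pose.contacts
        assert cl == pose.n_clashes


class TestDockPair:
    def test_two_spheres_unique_optimum(self):
        a = single_atom_monomer(0.0)
        b = single_atom_monomer(10.0)
        pose = dock_pair(a, b, MCParams(n_steps=5000, n_restarts=4), seed=1)
        assert pose.n_contacts == 1 and pose.n_clashes == 0

    def test_lock_key_recovery(self, lock_key):
        pose = dock_pair(
            lock_key.body_a, lock_key.body_b,
            MCParams(n_steps=80_000, n_restarts=20), seed=2,
        )
        rec = len(pose.contacts & lock_key.planted_contacts) / len(
            lock_key.planted_contacts
        )
        assert rec >= 0.8
        assert pose.n_clashes == 0

    def test_matches_coarse_grid_oracle(self):
        """Convex blob against a small flat plate: the MC optimum at least
        matches an exhaustive coarse 6-DOF transform scan."""
        from scipy.spatial.transform import Rotation

        a = blob(6, 7, spread=4.0)
        b = blob(3, 8, spread=2.0, first_residue=101)
        b = b.with_coords(b.coords + np.array([0, 0, 18.0]))
        pose = dock_pair(a, b, MCParams(n_steps=30_000, n_restarts=8), seed=3)
        best_scan = -1
        rots = [Rotation.identity()] + [
            Rotation.from_euler(ax, ang, degrees=True)
            for ax in "xyz" for ang in (90, 180, 270)
        ]
        lo = a.coords.min(axis=0) - 5
        hi = a.coords.max(axis=0) + 5
        for rot in rots:
            R = rot.as_matrix()
            for x in np.arange(lo[0], hi[0], 2.0):
                for y in np.arange(lo[1], hi[1], 2.0):
                    for z in np.arange(lo[2], hi[2], 2.0):
                        t = np.array([x, y, z]) - (b.coords @ R.T).mean(axis=0)
                        c, cl = intermolecular_contacts(a, b, R, t)
                        if cl == 0:
                            best_scan = max(best_scan, len(c))
        assert pose.n_contacts >= best_scan

    def test_reproducible_under_seed(self, lock_key):
        p1 = dock_pair(lock_key.body_a, lock_key.body_b,
                       MCParams(n_steps=3000, n_restarts=2), seed=11)
        p2 = dock_pair(lock_key.body_a, lock_key.body_b,
                       MCParams(n_steps=3000, n_restarts=2), seed=11)
        assert p1.contacts == p2.contacts
        np.testing.assert_array_equal(p1.translation, p2.translation)


class TestEnsembleDock:
    def test_single_conformer_pair(self):
        a = blob(6, 9)
        ens = ensemble_dock(
            [a], cap=40, window=10, seed=1,
            mc=MCParams(n_steps=500, n_restarts=1),
        )
        assert len(ens) <= 40
        assert len(ens.trace_mean) == len(ens.poses)

    def test_bimodal_classes_give_bimodal_histogram(self):
        big = blob(10, 10, spread=4.5)
        small = blob(3, 11, spread=2.0)
        ens = ensemble_dock(
            [big, small], cap=60, window=15, seed=2,
            mc=MCParams(n_steps=800, n_restarts=2),
        )
        counts = ens.contact_counts
        # pairs are (big, small) in some order: one contact class;
        # compare against homogeneous ensembles to confirm separation
        ens_big = ensemble_dock(
            [big, big.with_coords(big.coords + 0.01)], cap=30, window=10,
            seed=3, mc=MCParams(n_steps=800, n_restarts=2),
        )
        ens_small = ensemble_dock(
            [small, small.with_coords(small.coords + 0.01)], cap=30,
            window=10, seed=4, mc=MCParams(n_steps=800, n_restarts=2),
        )
        assert ens_big.contact_counts.mean() > ens_small.contact_counts.mean()

    def test_cap_window_validation(self):
        with pytest.raises(ValueError):
            ensemble_dock([blob(3, 1)], cap=10, window=10)


def pose_with(contacts, a=0, b=0):
    return DimerPose(a, b, np.eye(3), np.zeros(3),
                     frozenset(contacts), 0)


class TestStatistics:
    def test_point_mass_histogram(self):
        poses = [pose_with({(1, 2), (3, 4)})] * 5
        stats = density_histogram(DimerEnsemble(poses=poses))
        assert stats.histogram == {2: 1.0}
        assert stats.mean == 2 and stats.mode == 2

    def test_arithmetic_113(self):
        poses = [
            pose_with({(1, 1)}),
            pose_with({(2, 2)}),
            pose_with({(1, 1), (2, 2), (3, 3)}),
        ]
        stats = density_histogram(DimerEnsemble(poses=poses))
        assert stats.histogram[1] == pytest.approx(2 / 3)
        assert stats.histogram[3] == pytest.approx(1 / 3)
        assert stats.mean == pytest.approx(5 / 3)
        assert stats.mode == 1

    def test_histogram_normalized(self, lock_key):
        rng_poses = [
            pose_with({(i, j) for j in range(i)}) for i in range(1, 7)
        ]
        stats = density_histogram(DimerEnsemble(poses=rng_poses))
        assert sum(stats.histogram.values()) == pytest.approx(1.0)

    def test_mode_probability_ratio_between_species(self):
        """Comparing two ensembles by the density at their modes, the
        standard dimerization-propensity comparison."""
        s1 = density_histogram(DimerEnsemble(
            poses=[pose_with({(1, 1)})] * 8 + [pose_with(set())] * 2
        ))
        s2 = density_histogram(DimerEnsemble(
            poses=[pose_with({(1, 1)})] * 5 + [pose_with(set())] * 5
        ))
        ratio = s1.histogram[s1.mode] / s2.histogram[s2.mode]
        assert ratio == pytest.approx(1.6)

    def test_probability_map_fraction_and_symmetry(self):
        poses = [
            pose_with({(1, 5)}),
            pose_with({(5, 1)}),
            pose_with({(2, 3)}),
            pose_with(set()),
        ]
        pmap = contact_probability_map(DimerEnsemble(poses=poses))
        assert pmap[(1, 5)] == pytest.approx(0.5)  # pooled both orientations
        assert pmap[(2, 3)] == pytest.approx(0.25)
        assert all(a <= b for (a, b) in pmap)

    def test_single_pose_indicator(self):
        pmap = contact_probability_map(
            DimerEnsemble(poses=[pose_with({(1, 2), (4, 3)})])
        )
        assert pmap == {(1, 2): 1.0, (3, 4): 1.0}

    def test_top_contacts_ordering_and_truncation(self):
        pmap = {(1, 2): 0.9, (3, 4): 0.9, (5, 6): 0.2, (1, 9): 0.5}
        top = top_contacts(pmap, 3)
        assert [p for p, _ in top] == [(1, 2), (3, 4), (1, 9)]
        assert len(top_contacts(pmap, 50)) == 4
        with pytest.raises(ValueError):
            top_contacts(pmap, 0)

    def test_top_contacts_agree_with_full_sort(self):
        rng = np.random.default_rng(12)
        pmap = {
            (int(a), int(b)): float(rng.random())
            for a, b in rng.integers(1, 30, size=(40, 2))
        }
        top = top_contacts(pmap, 10)
        full = sorted(pmap.items(), key=lambda kv: (-kv[1], kv[0]))
        assert top == full[:10]

    def test_hotspot_single_contact(self):
        poses = [pose_with({(1, 5)}), pose_with(set())]
        prof = hotspot_profile([((1, 5), 0.5)], poses)
        assert prof == {1: 0.5, 5: 0.5}

    def test_hotspot_lock_key_patch_dominates(self, lock_key):
        poses = [
            dock_pair(lock_key.body_a, lock_key.body_b,
                      MCParams(n_steps=80_000, n_restarts=20), seed=s)
            for s in range(4)
        ]
        stats = InterfaceStatistics.from_ensemble(
            DimerEnsemble(poses=poses), top_k=50
        )
        patch = lock_key.patch_residues_a | lock_key.patch_residues_b
        in_patch = [v for r, v in stats.hotspots.items() if r in patch]
        out_patch = [v for r, v in stats.hotspots.items() if r not in patch]
        assert min(in_patch) > max(out_patch, default=0.0)

    def test_interaction_partners_counts(self):
        top = [((1, 5), 0.9), ((1, 7), 0.8), ((2, 5), 0.7)]
        partners = interaction_partners(1, top)
        assert partners == {5: 1, 7: 1}
        assert sum(partners.values()) == 2
        assert interaction_partners(99, top) == {}


class TestCationPi:
    def two_residue_bodies(self, res_a, res_b, distance):
        a = single_atom_monomer(0.0, residue=1, name="NZ", resname=res_a)
        b = single_atom_monomer(0.0, residue=1, name="CZ", resname=res_b)
        pose = DimerPose(0, 0, np.eye(3), np.array([distance, 0, 0]),
                         frozenset({(1, 1)}), 0)
        return a, b, pose

    def test_lys_tyr_flagged_within_cutoff(self):
        a, b, pose = self.two_residue_bodies("LYS", "TYR", 4.4)
        out = cation_pi_candidates(pose, a, b)
        assert len(out) == 1
        assert out[0]["within_cutoff"]

    def test_ala_tyr_not_flagged(self):
        a, b, pose = self.two_residue_bodies("ALA", "TYR", 4.4)
        assert cation_pi_candidates(pose, a, b) == []

    def test_classification_matches_type_lookup(self):
        rng = np.random.default_rng(13)
        names = ["ALA", "LYS", "ARG", "HIS", "PHE", "TYR", "TRP", "SER"]
        pos = {"HIS", "ARG", "LYS"}
        arom = {"PHE", "TYR", "TRP", "HIS"}
        for _ in range(20):
            ra, rb = rng.choice(names, 2)
            a, b, pose = self.two_residue_bodies(str(ra), str(rb), 4.0)
            flagged = bool(cation_pi_candidates(pose, a, b))
            expected = (ra in pos and rb in arom) or (
                rb in pos and ra in arom
            )
            assert flagged == expected
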