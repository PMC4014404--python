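"""Square-well model construction, energies and contact accounting."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from gofold.go_model import (
    HardCoreViolation,
    build_native_contact_map,
    fraction_native,
    pair_params,
    potential_energy,
    region_contact_counts,
)
from gofold.structure_io import RegionSpec, assign_radii
from gofold.synthetic import ToySpec, make_toy_native


class TestPairParams:
    def test_methyl_methyl_cutoff(self):
        sigma, edge = pair_params(1.84, 1.84, 0.80, 1.6)
        assert sigma == pytest.approx(2.944)
        assert edge == pytest.approx(4.7104)
        assert round(edge, 1) == 4.7

    def test_arithmetic(self):
        assert pair_params(1.0, 2.0, 0.5, 2.0) == (1.5, 3.0)

    def test_degenerate_lambda_rejected(self):
        with pytest.raises(ValueError):
            pair_params(1.0, 1.0, 1.0, 1.0)

    def test_non_positive_rejected(self):
        with pytest.raises(ValueError):
            pair_params(-1.0, 1.0, 0.8, 1.6)

    @given(
        r1=st.floats(0.5, 3.0),
        r2=st.floats(0.5, 3.0),
        alpha=st.floats(0.1, 0.99),
        lam=st.floats(1.01, 3.0),
    )
    @settings(max_examples=50, deadline=None)
    def test_sigma_below_edge_always(self, r1, r2, alpha, lam):
        sigma, edge = pair_params(r1, r2, alpha, lam)
        assert 0 < sigma < edge
        assert sigma == pytest.approx(alpha * (r1 + r2))


def brute_force_energy(structure, coords, alpha, lam, min_sep=3):
    """O(N^2) oracle: count native-well pairs from scratch."""
    radii = structure.radii
    res = structure.residue_numbers
    native_coords = structure.coords
    n = len(coords)
    e = 0
    for i in range(n):
        for j in range(i + 1, n):
            if abs(int(res[i]) - int(res[j])) < min_sep:
                continue
            sigma = alpha * (radii[i] + radii[j])
            edge = lam * sigma
            d_nat = np.linalg.norm(native_coords[i] - native_coords[j])
            if not sigma < d_nat <= edge:
                continue  # not a native contact
            d = np.linalg.norm(coords[i] - coords[j])
            if sigma < d <= edge:
                e -= 1
    return float(e)


class TestContactMap:
    def test_native_energy_matches_brute_force(self, toy10, model10):
        e = potential_energy(model10, toy10.coords)
        assert e == -model10.n_contacts
        assert e == brute_force_energy(toy10, toy10.coords, 0.80, 1.6)

    def test_perturbed_energy_matches_brute_force(self, toy10, model10):
        rng = np.random.default_rng(3)
        coords = toy10.coords + rng.normal(0, 0.4, toy10.coords.shape)
        e = potential_energy(model10, coords, check_clashes=False)
        assert e == brute_force_energy(toy10, coords, 0.80, 1.6)

    def test_adjacent_residues_excluded(self):
        # cross-strand hairpin neighbours at contact distance but |dres|<3
        toy = make_toy_native(ToySpec(6, 2, "hairpin", tail_residues=1))
        model = build_toy_model_local(toy)
        res = toy.residue_numbers
        for i, j in zip(model.pair_i, model.pair_j):
            assert abs(int(res[i]) - int(res[j])) >= 3

    def test_lambda_monotonicity(self, toy10):
        counts = []
        for lam in (1.2, 1.4, 1.6, 1.8):
            m = build_native_contact_map(toy10, 0.80, lam)
            counts.append(m.n_contacts)
        assert counts == sorted(counts)

    def test_contact_map_order_independent(self, toy10, model10):
        pairs = set(zip(model10.pair_i.tolist(), model10.pair_j.tolist()))
        rebuilt = build_native_contact_map(toy10, 0.80, 1.6)
        assert pairs == set(zip(rebuilt.pair_i.tolist(), rebuilt.pair_j.tolist()))

    def test_radii_required(self, toy10):
        from gofold.structure_io import ProteinStructure
        from dataclasses import replace

        bare = ProteinStructure(
            [replace(a, vdw_radius=None) for a in toy10.atoms],
            toy10.annotations, toy10.bonds,
        )
        with pytest.raises(ValueError, match="radii"):
            build_native_contact_map(bare)


def build_toy_model_local(toy):
    from gofold.synthetic import build_toy_model

    return build_toy_model(toy)


class TestEnergy:
    def test_expanded_conformation_zero_energy(self, toy10, model10):
        e = potential_energy(model10, toy10.coords * 3.0, check_clashes=False)
        assert e == 0.0

    def test_uniform_scaling_beyond_lambda_zeroes_energy(self, toy10, model10):
        # scale > lambda pushes every native distance beyond its well edge
        e = potential_energy(model10, toy10.coords * 1.7, check_clashes=False)
        assert e == 0.0

    def test_hard_core_violation_flagged_infinite(self, toy10, model10):
        coords = toy10.coords.copy()
        # move first atom onto an atom three residues away
        idx = np.where(toy10.residue_numbers >= 4)[0][0]
        coords[0] = coords[idx] + 0.1
        assert potential_energy(model10, coords) == np.inf

    def test_shape_mismatch(self, model10):
        with pytest.raises(ValueError):
            potential_energy(model10, np.zeros((3, 3)))


class TestFractionNative:
    def test_native_is_one(self, toy10, model10):
        assert fraction_native(model10, toy10.coords) == 1.0

    def test_expanded_is_zero(self, toy10, model10):
        assert fraction_native(model10, toy10.coords * 3.0) == 0.0

    def test_half_formed_constructed(self, toy10, model10):
        # expand only one strand pairing by moving tail residues away
        coords = toy10.coords.copy()
        d = np.linalg.norm(
            coords[model10.pair_i] - coords[model10.pair_j], axis=1
        )
        q0 = fraction_native(model10, coords)
        assert q0 == 1.0
        # break exactly half of the contacts by displacing atoms involved
        # in the first half of the pair list far away
        broken_target = model10.n_contacts // 2
        moved = set()
        broken = 0
        for i, j in zip(model10.pair_i, model10.pair_j):
            if broken >= broken_target:
                break
            if int(i) not in moved:
                coords[int(i)] += np.array([0.0, 0.0, 50.0])
                moved.add(int(i))
            broken = model10.n_contacts - int(
                round(fraction_native(model10, coords) * model10.n_contacts)
            )
        q = fraction_native(model10, coords)
        assert 0.0 < q < 1.0


class TestRegionCounts:
    def test_whole_chain_equals_total(self, toy10, model10):
        whole = RegionSpec("all", [[1, 10]])
        per, pairwise = region_contact_counts(model10, [whole])
        assert per["all"] == model10.n_contacts
        assert pairwise[("all", "all")] == model10.n_contacts

    def test_strand_counts_drop_after_truncation(self, toy10):
        """N-terminal truncation removes every contact of the lost residues,
        echoing the strand-A contact reduction of N-terminally cleaved
        variants."""
        from gofold.structure_io import truncate_n_terminus
        from gofold.synthetic import build_toy_model

        full = build_toy_model(toy10)
        strand_a = RegionSpec("A", [[1, 3]])
        per_full, _ = region_contact_counts(full, [strand_a])
        trunc = truncate_n_terminus(toy10, 2)
        m_trunc = build_toy_model(trunc)
        per_trunc, _ = region_contact_counts(
            m_trunc, [RegionSpec("A", [[2, 3]])]
        )
        assert per_trunc["A"] < per_full["A"]

    def test_empty_region_errors(self, model10):
        with pytest.raises(ValueError, match="no atoms"):
            region_contact_counts(model10, [RegionSpec("far", [[200, 210]])])
        # far region with atoms but no contacts is fine and counts zero
        per, _ = region_contact_counts(
            model10, [RegionSpec("mid", [[5, 6]])]
        )
        assert per["mid"] >= 0
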