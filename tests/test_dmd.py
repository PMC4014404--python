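"""Event kinematics, conservation laws, thermostat and replica exchange."""

import math

import numpy as np
import pytest
from scipy import stats

from gofold import dmd
from gofold.dmd import (
    Event,
    SimState,
    attempt_replica_swap,
    build_pair_tables,
    maxwell_velocities,
    next_pair_event,
    resolve_pair_velocities,
    run_dmd,
    run_re_dmd,
)


class TestNextPairEvent:
    def test_head_on_hard_core(self):
        ev = next_pair_event([3.0, 0, 0], [-2.0, 0, 0], sigma=1.0,
                             well_edge=None, in_well=False)
        assert ev.kind == "hard_core_bounce"
        assert ev.time == pytest.approx(1.0)

    def test_receding_pair_no_event(self):
        assert next_pair_event([3.0, 0, 0], [1.0, 0, 0], 1.0, None, False) is None

    def test_well_entry_timing(self):
        # approach from 6 A toward a well edge at 4: hit after 1 A of travel
        ev = next_pair_event([6.0, 0, 0], [-2.0, 0, 0], sigma=2.0,
                             well_edge=4.0, in_well=False)
        assert ev.kind == "well_entry"
        assert ev.time == pytest.approx(1.0)

    def test_overlapping_input_rejected(self):
        with pytest.raises(ValueError, match="hard core"):
            next_pair_event([0.5, 0, 0], [1.0, 0, 0], 1.0, None, False)

    def test_3d_event_matches_dense_time_stepping(self):
        rng = np.random.default_rng(5)
        sigma, edge = 2.0, 3.5
        for _ in range(20):
            # random state inside the well
            r = rng.normal(size=3)
            r *= rng.uniform(sigma * 1.05, edge * 0.95) / np.linalg.norm(r)
            v = rng.normal(size=3)
            ev = next_pair_event(r, v, sigma, edge, in_well=True)
            # brute-force scan
            dt = 1e-4
            t, x = 0.0, np.array(r, float)
            hit, kind = None, None
            for _ in range(200_000):
                t += dt
                x = r + v * t
                d = np.linalg.norm(x)
                if d <= sigma:
                    hit, kind = t, "hard_core_bounce"
                    break
                if d >= edge:
                    hit, kind = t, "well_exit"
                    break
            assert hit is not None
            assert ev.kind == kind
            assert ev.time == pytest.approx(hit, abs=2 * dt)


class TestResolveEvent:
    def test_well_entry_energy_gain(self):
        # head-on capture: Delta KE must equal +eps exactly
        vi = np.array([1.0, 0, 0])
        vj = np.array([-1.0, 0, 0])
        n = np.array([1.0, 0, 0])  # from i to j
        vi2, vj2, kind = resolve_pair_velocities(vi, vj, n, "well_entry", 1.0)
        ke_before = 0.5 * (vi @ vi + vj @ vj)
        ke_after = 0.5 * (vi2 @ vi2 + vj2 @ vj2)
        assert kind == "well_entry"
        assert ke_after - ke_before == pytest.approx(1.0)
        # momentum conserved
        np.testing.assert_allclose(vi + vj, vi2 + vj2, atol=1e-12)
        # relative radial speed: sqrt(vr^2 + 4 eps)
        vr_after = (vj2 - vi2) @ n
        assert vr_after == pytest.approx(-math.sqrt(4.0 + 4.0))

    def test_escape_with_insufficient_ke_bounces(self):
        vi = np.array([0.0, 0, 0])
        vj = np.array([0.5, 0, 0])  # radial KE = mu vr^2 = 0.125 < eps
        n = np.array([1.0, 0, 0])
        vi2, vj2, kind = resolve_pair_velocities(vi, vj, n, "well_exit", 1.0)
        assert kind == "well_exit_bounce"
        # elastic: speeds exchanged/reflected, magnitudes preserved
        assert np.linalg.norm(vj2 - vi2) == pytest.approx(0.5)

    def test_hard_core_reflects_radial_only(self):
        vi = np.array([0.0, 0.0, 0.0])
        vj = np.array([-1.0, 2.0, 0.0])
        n = np.array([1.0, 0.0, 0.0])
        vi2, vj2, kind = resolve_pair_velocities(
            vi, vj, n, "hard_core_bounce"
        )
        rel = vj2 - vi2
        assert rel @ n == pytest.approx(1.0)  # radial reversed
        assert rel[1] == pytest.approx(2.0)  # tangential unchanged


class TestRunDmd:
    def test_nve_energy_and_momentum_conservation(self, toy10, model10):
        traj, state = run_dmd(
            model10, toy10.coords, temperature=1.0, n_events=200_000,
            thermostat_rate=0.0, seed=11, sample_every=2_000,
        )
        total = traj.total
        assert np.abs(total - total[0]).max() < 1e-6
        assert np.abs(state.velocities.sum(axis=0)).max() < 1e-9

    def test_folded_at_low_temperature(self, toy10, model10):
        # unfold hot, then quench: the hairpin refolds and stays folded
        _, hot = run_dmd(model10, toy10.coords, 5.0, 200_000,
                         thermostat_rate=0.2, seed=1)
        q_hot = -hot.potential_energy / model10.n_contacts
        assert q_hot < 0.3
        traj, _ = run_dmd(
            model10,
            SimState(hot.coordinates,
                     maxwell_velocities(len(toy10), 0.25,
                                        np.random.default_rng(2))),
            0.25, 1_000_000, thermostat_rate=0.2, seed=3,
            sample_every=10_000,
        )
        assert traj.q[-1] > 0.8
        assert traj.q[-len(traj.q) // 4:].mean() > 0.8

    def test_no_hard_core_overlap_in_samples(self, toy10, model10):
        tables = build_pair_tables(model10)
        traj, _ = run_dmd(model10, toy10.coords, 2.0, 100_000,
                          thermostat_rate=0.2, seed=4, sample_every=5_000,
                          record_coords=True)
        hard = tables.kind != 2
        for frame in traj.coords:
            d2 = ((frame[tables.pj] - frame[tables.pi]) ** 2).sum(axis=1)
            assert (d2[hard] >= tables.rin2[hard] * (1 - 1e-9)).all()

    def test_velocities_maxwell_boltzmann(self, toy10, model10):
        # thermostatted run: pooled velocity components are normal(0, sqrt(T))
        T = 1.5
        comps = []
        for seed in range(6):
            _, st = run_dmd(model10, toy10.coords, T, 30_000,
                            thermostat_rate=0.5, seed=seed)
            comps.append(st.velocities.ravel())
        comps = np.concatenate(comps)
        _, p = stats.kstest(comps / math.sqrt(T), "norm")
        assert p > 1e-3

    def test_deterministic_under_seed(self, toy10, model10):
        t1, s1 = run_dmd(model10, toy10.coords, 1.0, 50_000, seed=42)
        t2, s2 = run_dmd(model10, toy10.coords, 1.0, 50_000, seed=42)
        np.testing.assert_array_equal(s1.coordinates, s2.coordinates)
        np.testing.assert_array_equal(t1.potential, t2.potential)

    def test_bonded_dimer_oscillation_period(self):
        """An isolated bonded pair rattles between its bond walls with the
        analytic piecewise-ballistic period."""
        from dataclasses import replace
        from gofold.go_model import GoModel
        from gofold.structure_io import AtomRecord, ProteinStructure

        d0, delta = 2.0, 0.25
        atoms = [
            AtomRecord(1, "CA", "C", 1, "ALA", [0.0, 0.0, 0.0], 1.84),
            AtomRecord(2, "CB", "C", 1, "ALA", [d0, 0.0, 0.0], 1.84),
        ]
        s = ProteinStructure(atoms, bonds=[(0, 1)])
        lo, hi = d0 * (1 - delta), d0 * (1 + delta)
        model = GoModel(
            structure=s, alpha=0.8, lam=1.6,
            pair_i=np.zeros(0, int), pair_j=np.zeros(0, int),
            sigma=np.zeros(0), well_edge=np.zeros(0),
            bond_i=np.array([0]), bond_j=np.array([1]),
            bond_min=np.array([lo]), bond_max=np.array([hi]),
        )
        v = 0.5
        init = SimState(
            coordinates=np.array([[0.0, 0, 0], [d0, 0, 0]]),
            velocities=np.array([[-v / 2, 0, 0], [v / 2, 0, 0]]),
        )
        traj, state = run_dmd(model, init, 1.0, n_events=9,
                              thermostat_rate=0.0, seed=0, sample_every=1)
        # relative speed v: flight time per wall-to-wall leg = (hi-lo)/v;
        # events alternate outer/inner walls
        leg = (hi - lo) / v
        dt = np.diff(traj.times)
        np.testing.assert_allclose(dt, leg, rtol=1e-9)


class TestReplicaExchange:
    def test_equal_temperatures_always_accept(self):
        rng = np.random.default_rng(0)
        assert all(
            attempt_replica_swap(-5.0, -9.0, 1.0, 1.0, rng)
            for _ in range(100)
        )

    def test_equal_energies_always_accept(self):
        rng = np.random.default_rng(0)
        assert all(
            attempt_replica_swap(-5.0, -5.0, 0.7, 1.3, rng)
            for _ in range(100)
        )

    def test_metropolis_frequency(self):
        # (1/Ti - 1/Tj)(Ei - Ej) = -1  =>  acceptance e^-1
        rng = np.random.default_rng(123)
        n = 100_000
        acc = sum(
            attempt_replica_swap(-2.0, 0.0, 1.0, 2.0, rng) for _ in range(n)
        )
        p = acc / n
        se = math.sqrt(math.exp(-1) * (1 - math.exp(-1)) / n)
        assert abs(p - math.exp(-1)) < 3 * se

    def test_non_positive_temperature_rejected(self):
        with pytest.raises(ValueError):
            attempt_replica_swap(0.0, 0.0, -1.0, 1.0,
                                 np.random.default_rng(0))

    def test_two_replicas_equal_T_same_distribution(self, model10, toy10):
        rs = run_re_dmd(model10, [1.0, 1.0 + 1e-9], 150_000, 1_500, seed=5)
        e0, e1 = rs.energy_samples
        _, p = stats.ks_2samp(e0, e1)
        assert p > 1e-3

    def test_re_deterministic(self, model10):
        r1 = run_re_dmd(model10, [0.8, 1.2], 30_000, 1_000, seed=9)
        r2 = run_re_dmd(model10, [0.8, 1.2], 30_000, 1_000, seed=9)
        np.testing.assert_array_equal(
            r1.energy_samples[0], r2.energy_samples[0]
        )
        np.testing.assert_array_equal(r1.swap_accepts, r2.swap_accepts)

    def test_grid_must_ascend(self, model10):
        with pytest.raises(ValueError):
            run_re_dmd(model10, [1.0, 1.0], 10_000, 1_000)
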