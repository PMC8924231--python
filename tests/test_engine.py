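"""Langevin engine: thermostat physics, energy conservation, neighbor-list
correctness against a brute-force oracle, determinism and checkpoints."""

import numpy as np
import pytest

from condmd.engine import (CheckpointError, EngineParams, SimulationState,
                           Topology, compute_forces, kinetic_energy,
                           read_checkpoint, step, switch_interactions,
                           write_checkpoint)
from condmd.model import (CGModel, InteractionTable, PotentialSpec, bond_force,
                          make_sequence, pair_force)

from conftest import random_chain_state


def brute_forces(state, model):
    """O(N^2) reference forces + energy, independent of the engine kernels."""
    from condmd.model import bond_energy, pair_energy

    pos = state.positions
    box = state.box
    n = pos.shape[0]
    L = state.topology.chain_len
    roles = state.topology.roles
    table = model.interactions
    f = np.zeros_like(pos)
    pe = 0.0
    for i in range(n):
        for j in range(i + 1, n):
            same_chain = i // L == j // L
            bonded = same_chain and j - i == 1
            d = pos[i] - pos[j]
            d -= box * np.rint(d / box)
            r = np.linalg.norm(d)
            if bonded:
                pe += bond_energy(model.bonds, r)
                fb = bond_force(model.bonds, d)
                f[i] += fb
                f[j] -= fb
            elif r < model.potential.cutoff:
                eps = table.well_depth(roles[i], roles[j])
                pe += pair_energy(model.potential, r, eps)
                fp = pair_force(model.potential, d, eps)
                f[i] += fp
                f[j] -= fp
    return f, pe


class TestLangevinPhysics:
    def test_free_particle_diffusion_matches_einstein(self, free_walkers):
        state, model = free_walkers
        params = EngineParams(dt=0.005, friction_gamma=1.0, temperature_kT=1.0,
                              seed=42)
        step(state, params, model, 2000)  # thermalize
        u0 = state.unwrapped.copy()
        t0 = state.time
        step(state, params, model, 20000)
        msd = np.mean(np.sum((state.unwrapped - u0) ** 2, axis=1))
        D = msd / (6.0 * (state.time - t0))
        assert D == pytest.approx(1.0, rel=0.05)  # kT / (m gamma)

    def test_velocity_distribution_thermalizes(self, free_walkers):
        state, model = free_walkers
        params = EngineParams(dt=0.005, friction_gamma=1.0, seed=3)
        step(state, params, model, 5000)
        assert state.velocities.var() == pytest.approx(1.0, rel=0.1)

    def test_nve_energy_conservation(self):
        # gamma = 0: velocity-Verlet limit on a perturbed LJ dimer
        topo = Topology(2, 1, np.full(2, 2, dtype=np.int8))
        box = np.array([20.0] * 3)
        r = 2.0 ** (1 / 6) + 0.05
        pos = np.array([[10.0, 10.0, 10.0], [10.0 + r, 10.0, 10.0]])
        state = SimulationState(pos, np.zeros((2, 3), dtype=np.int64),
                                np.zeros((2, 3)), box, topo)
        model = CGModel(InteractionTable(1.0, 1.0))
        params = EngineParams(dt=0.005, friction_gamma=0.0, seed=0)
        _, pe0 = compute_forces(state, model)
        e0 = pe0 + kinetic_energy(state)
        drift = 0.0
        for _ in range(10):
            step(state, params, model, 10000)
            _, pe = compute_forces(state, model)
            drift = max(drift, abs(pe + kinetic_energy(state) - e0))
        assert drift < 1e-4

    def test_determinism_under_fixed_seed(self):
        s1 = random_chain_state(seed=5)
        s2 = random_chain_state(seed=5)
        model = CGModel(InteractionTable(0.5, 5.0))
        params = EngineParams(dt=0.002, friction_gamma=1.0, seed=9,
                              force_cap=100.0)
        step(s1, params, model, 500)
        step(s2, params, model, 500)
        assert np.array_equal(s1.positions, s2.positions)
        assert np.array_equal(s1.velocities, s2.velocities)

    def test_ideal_chain_end_to_end_scaling(self):
        # bonds only (vanishing nonbonded attraction): <R^2> = (N-1) b^2
        n_chains, L = 100, 39
        seq = make_sequence("homopolymer", L)
        from condmd.builders import SystemSpec, build_dilute

        box = 140.0
        state = build_dilute(SystemSpec(n_chains, seq, (box, box, box)), seed=8)
        model = CGModel(InteractionTable(1e-9, 1e-9))
        params = EngineParams(dt=0.005, friction_gamma=1.0, seed=4)
        step(state, params, model, 12000)  # ~ one Rouse time
        r2 = []
        for _ in range(5):
            step(state, params, model, 3000)
            # chains may straddle the periodic boundary: rebuild continuity
            # from minimum-image bond vectors
            u = state.unwrapped.reshape(n_chains, L, 3)
            bonds = np.diff(u, axis=1)
            bonds -= state.box * np.rint(bonds / state.box)
            ends = bonds.sum(axis=1)
            r2.append(np.mean(np.sum(ends ** 2, axis=1)))
        b2 = 1.0 + 3.0 / model.bonds.k_bond  # thermal bond-length correction
        assert np.mean(r2) / ((L - 1) * b2) == pytest.approx(1.0, abs=0.1)


class TestForces:
    @pytest.mark.parametrize("potential", [
        PotentialSpec(cutoff=3.0, shift_at_cutoff=True),
        PotentialSpec.wang_frenkel(cutoff=1.5),
    ])
    @pytest.mark.parametrize("seed", [0, 1, 2])
    def test_cell_list_equals_brute_force(self, potential, seed):
        state = random_chain_state(n_chains=5, chain_len=10, box_edge=11.0,
                                   seed=seed)
        model = CGModel(InteractionTable(0.5, 5.0), potential)
        f, pe = compute_forces(state, model)
        f_ref, pe_ref = brute_forces(state, model)
        scale = np.abs(f_ref).max()
        assert np.allclose(f, f_ref, rtol=1e-10, atol=1e-10 * scale)
        assert pe == pytest.approx(pe_ref, rel=1e-10)

    def test_cell_list_equals_brute_force_39mer(self):
        state = random_chain_state(n_chains=5, chain_len=39, box_edge=16.0,
                                   seed=3, patterning="uniform")
        model = CGModel(InteractionTable(0.66, 6.6))
        f, pe = compute_forces(state, model)
        f_ref, pe_ref = brute_forces(state, model)
        assert np.allclose(f, f_ref, rtol=1e-10, atol=1e-10 * np.abs(f_ref).max())
        assert pe == pytest.approx(pe_ref, rel=1e-10)

    def test_isolated_chain_force_sum_vanishes(self):
        state = random_chain_state(n_chains=1, chain_len=20, box_edge=60.0, seed=4)
        model = CGModel(InteractionTable(0.5, 5.0))
        f, _ = compute_forces(state, model)
        assert np.allclose(f.sum(axis=0), 0.0, atol=1e-9)

    def test_single_bead_zero_force(self):
        topo = Topology(1, 1, np.full(1, 2, dtype=np.int8))
        state = SimulationState(np.array([[5.0, 5.0, 5.0]]),
                                np.zeros((1, 3), dtype=np.int64),
                                np.zeros((1, 3)), np.array([10.0] * 3), topo)
        f, pe = compute_forces(state, CGModel(InteractionTable(1.0, 1.0)))
        assert np.allclose(f, 0.0) and pe == 0.0


class TestSwitchInteractions:
    def test_energy_rescales_only_ab_terms(self):
        state = random_chain_state(n_chains=5, chain_len=39, box_edge=16.0,
                                   seed=10, patterning="uniform")
        m1 = CGModel(InteractionTable(0.66, 6.6))
        _, pe1 = compute_forces(state, m1)
        m2 = switch_interactions(state, m1, InteractionTable(0.66, 5.0))
        _, pe2 = compute_forces(state, m2)
        # independent oracle: recompute both energies brute force
        _, ref1 = brute_forces(state, m1)
        _, ref2 = brute_forces(state, m2)
        assert pe1 == pytest.approx(ref1, rel=1e-9)
        assert pe2 == pytest.approx(ref2, rel=1e-9)
        # the difference comes solely from A-B pairs, linear in eps_S
        per_unit = (ref1 - ref2) / (6.6 - 5.0)
        m3 = switch_interactions(state, m2, InteractionTable(0.66, 6.0))
        _, pe3 = compute_forces(state, m3)
        assert pe3 == pytest.approx(pe2 + per_unit * 1.0, rel=1e-6)

    def test_switch_is_logged_and_positions_untouched(self):
        state = random_chain_state(seed=11)
        pos = state.positions.copy()
        m = CGModel(InteractionTable.from_eps_S(6.6))
        m2 = switch_interactions(state, m, InteractionTable.from_eps_S(5.0))
        assert m2.interactions.eps_S == 5.0
        assert np.array_equal(state.positions, pos)
        assert state.switch_log[0]["eps_S"] == 5.0

    def test_identity_switch_is_noop(self):
        state = random_chain_state(seed=12)
        m = CGModel(InteractionTable.from_eps_S(5.0))
        m2 = switch_interactions(state, m, InteractionTable.from_eps_S(5.0))
        _, pe1 = compute_forces(state, m)
        _, pe2 = compute_forces(state, m2)
        assert pe1 == pe2


class TestCheckpoints:
    def test_roundtrip_and_continuation(self, tmp_path):
        state = random_chain_state(seed=13)
        model = CGModel(InteractionTable(0.5, 5.0))
        params = EngineParams(dt=0.002, friction_gamma=1.0, seed=2,
                              force_cap=100.0)
        step(state, params, model, 200)
        path = tmp_path / "chk.h5"
        write_checkpoint(state, path)
        restored = read_checkpoint(path)
        assert np.array_equal(restored.positions, state.positions)
        assert np.array_equal(restored.images, state.images)
        assert restored.step_count == state.step_count
        step(state, params, model, 300)
        step(restored, params, model, 300)
        assert np.array_equal(restored.positions, state.positions)

    def test_unwrapped_positions_survive_roundtrip(self, tmp_path):
        state = random_chain_state(seed=14)
        model = CGModel(InteractionTable(0.5, 5.0))
        step(state, EngineParams(dt=0.002, friction_gamma=1.0, seed=5,
                                 force_cap=100.0), model, 2000)
        path = tmp_path / "chk.h5"
        write_checkpoint(state, path)
        assert np.array_equal(read_checkpoint(path).unwrapped, state.unwrapped)

    def test_corrupted_file_raises(self, tmp_path):
        path = tmp_path / "bad.h5"
        path.write_bytes(b"this is not an hdf5 file")
        with pytest.raises(CheckpointError):
            read_checkpoint(path)


def test_box_too_small_for_cutoff_rejected():
    state = random_chain_state(n_chains=2, chain_len=5, box_edge=6.0, seed=1)
    model = CGModel(InteractionTable(0.5, 5.0))  # cutoff 3 + skin > box/2
    with pytest.raises(Exception):
        step(state, EngineParams(), model, 10)
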