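"""Sequences, interaction table, and pair/bond potentials."""

import itertools

import numpy as np
import pytest
from scipy.optimize import minimize_scalar

from condmd.model import (BeadRole, BondSpec, InteractionTable, PotentialSpec,
                          bond_energy, bond_force, build_interaction_table,
                          make_sequence, pair_energy, pair_force, wf_r_min,
                          ModelValidationError, ReducedUnits)


class TestSequences:
    def test_uniform_composition(self):
        seq = make_sequence("uniform", 39)
        counts = seq.role_counts()
        assert counts[BeadRole.STICKER_A] == 3
        assert counts[BeadRole.STICKER_B] == 2
        assert counts[BeadRole.SPACER] == 34
        assert seq.n_beads == 39

    def test_homopolymer_is_all_spacer(self):
        seq = make_sequence("homopolymer", 39)
        assert all(r == BeadRole.SPACER for r in seq.roles)

    def test_half_chain_stickers_in_first_half(self):
        seq = make_sequence("half_chain", 39)
        sticker_idx = [i for i, r in enumerate(seq.roles) if r != BeadRole.SPACER]
        assert len(sticker_idx) == 5
        assert max(sticker_idx) < 39 // 2

    @pytest.mark.parametrize("bad", [
        dict(sticker_positions_A=(1, 1, 2), sticker_positions_B=(5, 6)),
        dict(sticker_positions_A=(1, 2, 50), sticker_positions_B=(5, 6)),
        dict(sticker_positions_A=(1, 2, 3), sticker_positions_B=(3, 6)),
    ])
    def test_invalid_positions_rejected(self, bad):
        with pytest.raises(ModelValidationError):
            make_sequence("uniform", 39, **bad)


class TestInteractionTable:
    def test_strong_only_for_heterotypic_sticker_pair(self):
        t = build_interaction_table(0.5, 5.0)
        for a, b in itertools.product(BeadRole, repeat=2):
            expected = 5.0 if {a, b} == {BeadRole.STICKER_A, BeadRole.STICKER_B} else 0.5
            assert t.well_depth(a, b) == expected
            assert t.well_depth(a, b) == t.well_depth(b, a)

    def test_matrix_matches_lookup(self):
        t = build_interaction_table(0.525, 5.25)
        m = t.as_matrix()
        assert np.allclose(m, m.T)
        assert m[int(BeadRole.STICKER_B), int(BeadRole.STICKER_A)] == 5.25

    def test_degenerate_homopolymer_limit(self):
        t = build_interaction_table(0.66, 0.66)
        assert all(t.well_depth(a, b) == 0.66
                   for a, b in itertools.product(BeadRole, repeat=2))

    def test_coupling_rule(self):
        t = InteractionTable.from_eps_S(5.0)
        assert t.eps_D == 0.5
        with pytest.raises(ModelValidationError):
            InteractionTable(0.3, 5.0, coupled=True)

    def test_nonpositive_rejected(self):
        with pytest.raises(ModelValidationError):
            build_interaction_table(-0.1, 1.0)


class TestPairPotential:
    def test_lj_minimum_depth(self):
        spec = PotentialSpec(shift_at_cutoff=False)
        assert pair_energy(spec, 2.0 ** (1 / 6), 1.0) == pytest.approx(-1.0)

    def test_lj_zero_crossing_at_sigma(self):
        spec = PotentialSpec(shift_at_cutoff=False)
        assert pair_energy(spec, 1.0, 0.5) == pytest.approx(0.0, abs=1e-12)

    def test_shifted_energy_continuous_at_cutoff(self):
        spec = PotentialSpec(cutoff=3.0, shift_at_cutoff=True)
        inside = pair_energy(spec, 3.0 - 1e-10, 2.0)
        assert pair_energy(spec, 3.0, 2.0) == 0.0
        assert abs(inside) < 1e-8

    def test_wang_frenkel_minimum_is_minus_eps(self):
        spec = PotentialSpec.wang_frenkel(cutoff=1.5)
        res = minimize_scalar(lambda r: pair_energy(spec, r, 1.0),
                              bounds=(0.9, 1.49), method="bounded")
        assert res.fun == pytest.approx(-1.0, abs=1e-6)
        assert res.x == pytest.approx(wf_r_min(1.5, 1.0, 1, 1), abs=1e-5)

    def test_wang_frenkel_shorter_ranged_than_lj(self):
        wf = PotentialSpec.wang_frenkel(cutoff=1.5)
        lj = PotentialSpec(cutoff=3.0)
        r = 1.8
        assert pair_energy(wf, r, 1.0) == 0.0
        assert pair_energy(lj, r, 1.0) < -0.05

    def test_zero_separation_raises(self):
        with pytest.raises(ModelValidationError):
            pair_energy(PotentialSpec(), 0.0, 1.0)
        with pytest.raises(ModelValidationError):
            pair_force(PotentialSpec(), np.zeros(3), 1.0)

    @pytest.mark.parametrize("spec", [
        PotentialSpec(cutoff=3.0, shift_at_cutoff=True),
        PotentialSpec(cutoff=3.0, shift_at_cutoff=False),
        PotentialSpec.wang_frenkel(cutoff=1.5),
        PotentialSpec.wang_frenkel(cutoff=2.0, nu=1, mu=2),
    ])
    def test_force_matches_finite_difference(self, spec):
        rng = np.random.default_rng(1)
        h = 1e-6
        for r in np.linspace(0.85, spec.cutoff - 0.02, 25):
            dudr_num = (pair_energy(spec, r + h, 1.3) -
                        pair_energy(spec, r - h, 1.3)) / (2 * h)
            vec = rng.normal(size=3)
            vec *= r / np.linalg.norm(vec)
            f = pair_force(spec, vec, 1.3)
            f_rad = float(np.dot(f, vec / r))
            assert f_rad == pytest.approx(-dudr_num, rel=1e-5, abs=1e-7)

    def test_force_at_minimum_zero_and_newton_third_law(self):
        spec = PotentialSpec(shift_at_cutoff=True)
        vec = np.array([2.0 ** (1 / 6), 0.0, 0.0])
        assert np.allclose(pair_force(spec, vec, 1.0), 0.0, atol=1e-12)
        rng = np.random.default_rng(2)
        v = rng.normal(size=3)
        assert np.allclose(pair_force(spec, v, 0.7), -pair_force(spec, -v, 0.7))


class TestBonds:
    def test_closed_form(self):
        spec = BondSpec(k_bond=100.0, r0=1.0)
        assert bond_energy(spec, 1.0) == 0.0
        assert bond_energy(spec, 2.0) == pytest.approx(50.0)

    def test_gradient_matches_finite_difference(self):
        spec = BondSpec(k_bond=1000.0, r0=1.0)
        h = 1e-6
        for r in (0.8, 1.0, 1.3):
            dudr = (bond_energy(spec, r + h) - bond_energy(spec, r - h)) / (2 * h)
            f = bond_force(spec, np.array([r, 0.0, 0.0]))
            assert f[0] == pytest.approx(-dudr, rel=1e-5, abs=1e-6)


def test_reduced_units_consistency():
    u = ReducedUnits()
    assert u.tau_star == pytest.approx(1.0)
    assert ReducedUnits(sigma=2.0, epsilon_ref=4.0).tau_star == pytest.approx(1.0)
    with pytest.raises(ModelValidationError):
        ReducedUnits(sigma=-1.0)
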