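"""Potential-level analytics, continuity, and energy bookkeeping."""
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import memelast as m
from memelast.core import BeadKind
from memelast.forcefield import BeadMove, BoxScale, FeneDomainError


class TestScalarPotentials:
    @pytest.mark.parametrize("r, expected", [
        (0.7, 0.0),                          # optimal bond length, no stretching
        (0.8, -2.0 * math.log(0.75)),        # half-way to maximal extension
        (0.6, -2.0 * math.log(0.75)),        # symmetric about r0
    ])
    def test_fene_values(self, ff, r, expected):
        assert m.fene_energy(r, ff) == pytest.approx(expected, abs=1e-12)

    def test_fene_diverges_at_maximal_stretch(self, ff):
        assert m.fene_energy(0.9 - 1e-9, ff) > 35.0

    @pytest.mark.parametrize("r", [0.9, 0.49, 1.5, 0.0])
    def test_fene_domain_error(self, ff, r):
        with pytest.raises(FeneDomainError):
            m.fene_energy(r, ff)

    def test_fene_convex_and_symmetric(self, ff):
        d = np.linspace(1e-4, 0.199, 200)
        up = np.array([m.fene_energy(0.7 + x, ff) for x in d])
        dn = np.array([m.fene_energy(0.7 - x, ff) for x in d])
        np.testing.assert_allclose(up, dn, rtol=1e-12)
        assert np.all(np.diff(up, 2) > 0)  # strictly convex

    @pytest.mark.parametrize("theta, expected", [
        (0.0, 0.0), (math.pi, 9.4), (math.pi / 2, 4.7),
    ])
    def test_bond_angle_values(self, ff, theta, expected):
        assert m.bond_angle_energy(theta, ff) == pytest.approx(expected)

    def test_bond_angle_monotone_on_domain(self, ff):
        th = np.linspace(0, math.pi, 100)
        e = [m.bond_angle_energy(t, ff) for t in th]
        assert np.all(np.diff(e) > 0)

    @pytest.mark.parametrize("r, ka, kb, expected", [
        (2.0, BeadKind.tail, BeadKind.tail, 0.0),        # exactly at cutoff
        (1.0, BeadKind.tail, BeadKind.tail,
         -1.0 - (2.0 ** -12 - 2.0 * 2.0 ** -6)),          # LJ minimum, shifted
        (1.05, BeadKind.head, BeadKind.tail, 0.0),        # r = r_c for this pair
        (0.5, BeadKind.solvent, BeadKind.solvent, 0.0),   # phantom pair
    ])
    def test_soft_core_values(self, ff, r, ka, kb, expected):
        assert m.soft_core_energy(r, ka, kb, ff) == pytest.approx(expected, abs=1e-12)

    def test_soft_core_continuous_at_every_cutoff(self, ff):
        for key, p in ff.pair_table.items():
            if not p.active:
                continue
            ka, kb = (list(key) * 2)[:2]
            below = m.soft_core_energy(p.r_cut - 1e-8, ka, kb, ff)
            above = m.soft_core_energy(p.r_cut + 1e-8, ka, kb, ff)
            assert above == 0.0
            assert abs(below) < 1e-6

    def test_short_cutoff_pairs_repulsive(self, ff):
        # r_c = 1 sigma truncates at the LJ minimum: purely repulsive
        for r in np.linspace(0.6, 1.049, 50):
            assert m.soft_core_energy(r, BeadKind.head, BeadKind.head, ff) >= 0.0

    @given(st.floats(min_value=1e-6, max_value=0.1999))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_fene_symmetry_property(self, d):
        ff = m.ForceFieldParams()
        assert m.fene_energy(0.7 + d, ff) == pytest.approx(
            m.fene_energy(0.7 - d, ff), rel=1e-12)


class TestConfigurationEnergy:
    def test_single_solvent_bead_zero(self, ff):
        cfg = m.make_phantom_gas(1, (10, 10, 10), seed=0)
        assert m.total_energy(cfg, ff) == 0.0

    def test_straight_lipid_brute_force(self, ff):
        # one straight chain far from images: only intramolecular
        # second-and-further-neighbour soft-core terms contribute
        pos = np.zeros((7, 3))
        pos[:, 2] = 50.0 - 0.7 * np.arange(7)
        pos[:, 0] = pos[:, 1] = 50.0
        kinds = np.array([0] + [1] * 6)
        cfg = m.Configuration(positions=pos, kinds=kinds,
                              molecules=[list(range(7))],
                              box=np.array([100.0, 100.0, 100.0]))
        expected = 0.0
        for i in range(7):
            for j in range(i + 2, 7):   # directly bonded pairs excluded
                r = 0.7 * (j - i)
                expected += m.soft_core_energy(r, kinds[i], kinds[j], ff)
        assert m.total_energy(cfg, ff) == pytest.approx(expected, abs=1e-12)

    def test_translation_invariance(self, small_bilayer, ff):
        e0 = m.total_energy(small_bilayer, ff)
        shifted = small_bilayer.copy()
        shifted.positions += np.array([1.234, -0.777, 3.141])
        shifted.wrap()
        assert m.total_energy(shifted, ff) == pytest.approx(e0, abs=1e-8)

    def test_pbc_box_vector_translation(self, small_bilayer, ff):
        e0 = m.total_energy(small_bilayer, ff)
        shifted = small_bilayer.copy()
        shifted.positions[13] += shifted.box * np.array([2.0, -1.0, 1.0])
        shifted.wrap()
        assert m.total_energy(shifted, ff) == pytest.approx(e0, abs=1e-9)

    def test_kernel_matches_reference(self, small_bilayer, ff):
        assert m.kernel_total_energy(small_bilayer, ff) == pytest.approx(
            m.total_energy(small_bilayer, ff), abs=1e-8)

    def test_kernel_matches_reference_cell_path(self, ff):
        # box large enough for >= 3 cells per axis exercises the cell list
        cfg = m.build_bilayer(8, 8, "fluid", seed=3)
        assert m.kernel_total_energy(cfg, ff) == pytest.approx(
            m.total_energy(cfg, ff), abs=1e-7)


class TestDeltaEnergy:
    def test_null_move(self, tiny_lipid_box, ff):
        mv = BeadMove(3, tiny_lipid_box.positions[3].copy())
        assert m.delta_energy(tiny_lipid_box, mv, ff) == pytest.approx(0.0, abs=1e-12)

    def test_unit_box_scale(self, tiny_lipid_box, ff):
        assert m.delta_energy(tiny_lipid_box, BoxScale(1, 1.0), ff) == pytest.approx(
            0.0, abs=1e-12)

    def test_random_moves_match_full_recompute(self, tiny_lipid_box, ff):
        rng = np.random.default_rng(12)
        cfg = tiny_lipid_box
        e0 = m.total_energy(cfg, ff)
        for _ in range(1000):
            i = int(rng.integers(cfg.n_beads))
            new = cfg.positions[i] + rng.uniform(-0.05, 0.05, 3)
            trial = cfg.copy()
            trial.positions[i] = new % trial.box
            try:
                de = m.delta_energy(cfg, BeadMove(i, new), ff)
                e1 = m.total_energy(trial, ff)
            except FeneDomainError:
                continue
            assert de == pytest.approx(e1 - e0, abs=1e-9)

    def test_box_scale_matches_recompute(self, tiny_lipid_box, ff):
        de = m.delta_energy(tiny_lipid_box, BoxScale(0, 1.02), ff)
        trial = tiny_lipid_box.copy()
        trial.positions[:, 0] *= 1.02
        trial.box[0] *= 1.02
        assert de == pytest.approx(
            m.total_energy(trial, ff) - m.total_energy(tiny_lipid_box, ff), abs=1e-9)
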