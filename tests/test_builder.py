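"""Bilayer construction and membrane descriptors."""
import numpy as np
import pytest

import memelast as m
from memelast.builder import PHASES, LeafletError, PackingError


class TestPhasePresets:
    @pytest.mark.parametrize("name, P, T, Ta", [
        ("gel", 2.0, 1.08, 1.2),
        ("fluid", 1.0, 1.3, 1.4),
        ("interdigitated", 0.5, 1.16, 1.3),
    ])
    def test_state_points(self, name, P, T, Ta):
        ph = PHASES[name]
        assert (ph.P, ph.T, ph.T_anneal) == (P, T, Ta)


class TestBuild:
    def test_standard_rectangular_size(self):
        cfg = m.build_bilayer(12, 24, "fluid", seed=0)
        assert cfg.n_lipids == 2 * 12 * 24 == 576
        lipid_beads = sum(len(mol) for mol in cfg.lipids)
        assert lipid_beads == 576 * 7 == 4032

    def test_large_square_lipid_count(self):
        # solvent-free keeps the large build cheap; lipid count is the check
        cfg = m.build_bilayer(64, 64, "fluid", seed=0, solvent_density=0.0)
        assert cfg.n_lipids == 2 * 64 * 64 == 8192

    def test_straight_chain_geometry(self, small_bilayer, ff):
        bonds = small_bilayer.bond_array()
        d = small_bilayer.minimum_image(
            small_bilayer.positions[bonds[:, 1]] - small_bilayer.positions[bonds[:, 0]])
        r = np.linalg.norm(d, axis=1)
        np.testing.assert_allclose(r, ff.r0, atol=1e-12)
        angles = small_bilayer.angle_array()
        u = small_bilayer.minimum_image(
            small_bilayer.positions[angles[:, 1]] - small_bilayer.positions[angles[:, 0]])
        v = small_bilayer.minimum_image(
            small_bilayer.positions[angles[:, 2]] - small_bilayer.positions[angles[:, 1]])
        cos = (u * v).sum(1) / (np.linalg.norm(u, axis=1) * np.linalg.norm(v, axis=1))
        np.testing.assert_allclose(cos, 1.0, atol=1e-12)

    def test_build_is_seed_deterministic(self):
        a = m.build_bilayer(4, 4, "fluid", seed=7)
        b = m.build_bilayer(4, 4, "fluid", seed=7)
        np.testing.assert_array_equal(a.positions, b.positions)
        c = m.build_bilayer(4, 4, "fluid", seed=8)
        assert not np.array_equal(a.positions, c.positions)  # solvent differs

    def test_build_passes_energy_without_bond_breaks(self, small_bilayer, ff):
        m.total_energy(small_bilayer, ff)  # raises FeneDomainError on failure

    def test_interdigitated_construction(self):
        cfg = m.build_bilayer(4, 4, "interdigitated", seed=0)
        md = m.membrane_descriptors(cfg)
        assert md.thickness == pytest.approx(4.8, abs=1e-6)
        assert md.order_parameter == pytest.approx(1.0)

    def test_overpacked_lattice_rejected(self):
        with pytest.raises(PackingError):
            m.build_bilayer(4, 4, "fluid", area_per_lipid_init=0.4, seed=0)


class TestDescriptors:
    def test_fresh_bilayer_descriptors(self, small_bilayer):
        md = m.membrane_descriptors(small_bilayer)
        assert md.order_parameter == pytest.approx(1.0)       # all bonds along z
        assert md.chain_length_mean == pytest.approx(4.2)     # 6 bonds at r0
        assert md.area_per_lipid == pytest.approx(1.68)
        assert md.thickness == pytest.approx(2 * 4.2 + 1.0)

    def test_z_translation_invariance(self, small_bilayer):
        ref = m.membrane_descriptors(small_bilayer)
        shifted = small_bilayer.copy()
        shifted.positions[:, 2] += 11.3   # drifts across the periodic boundary
        shifted.wrap()
        md = m.membrane_descriptors(shifted)
        assert md.thickness == pytest.approx(ref.thickness, abs=1e-9)
        assert md.order_parameter == pytest.approx(ref.order_parameter, abs=1e-12)
        assert md.chain_length_mean == pytest.approx(ref.chain_length_mean, abs=1e-12)

    def test_no_lipids_raises(self):
        gas = m.make_phantom_gas(10, (5, 5, 5), seed=0)
        with pytest.raises(LeafletError):
            m.membrane_descriptors(gas)
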