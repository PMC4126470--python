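"""Axial-rescale protocol: geometry, guards, and the network oracle."""
import numpy as np
import pytest

import memelast as m
from memelast.builder import PhasePoint
from memelast.forcefield import FeneDomainError

NET_PHASE = PhasePoint("network", P=0.0, T=0.1, T_anneal=0.1)
NET_SETTINGS = m.MCSettings(displacement_max=0.06, box_move_max=0.003,
                            fixed_axes=("z",), move_dims=(True, True, False))


class TestRescale:
    def test_zero_strain_identity(self, small_bilayer):
        out = m.rescale_axial(small_bilayer, 0.0, "y")
        np.testing.assert_array_equal(out.positions, small_bilayer.positions)
        np.testing.assert_array_equal(out.box, small_bilayer.box)

    def test_exact_algebraic_inverse(self, small_bilayer):
        eta = 0.05
        out = m.rescale_axial(small_bilayer, eta, "y")
        back = m.rescale_axial(out, -eta / (1 + eta), "y")
        np.testing.assert_allclose(back.positions, small_bilayer.positions, atol=1e-12)
        np.testing.assert_allclose(back.box, small_bilayer.box, atol=1e-12)

    def test_only_target_axis_scaled(self, small_bilayer):
        eta = 0.05
        out = m.rescale_axial(small_bilayer, eta, "y")
        np.testing.assert_allclose(out.positions[:, 1],
                                   small_bilayer.positions[:, 1] * 1.05, atol=1e-12)
        np.testing.assert_array_equal(out.positions[:, 0], small_bilayer.positions[:, 0])
        np.testing.assert_array_equal(out.positions[:, 2], small_bilayer.positions[:, 2])
        assert out.box[1] == pytest.approx(small_bilayer.box[1] * 1.05)
        assert out.box[0] == small_bilayer.box[0]

    def test_z_axis_forbidden(self, small_bilayer):
        with pytest.raises(ValueError):
            m.rescale_axial(small_bilayer, 0.05, "z")
        with pytest.raises(ValueError):
            m.measure_poisson(small_bilayer, "fluid", 0.05, "z")

    def test_bond_breaking_guarded(self, ff):
        # two beads bonded along y: admissible strain is (r0+dr_m)/r0 - 1
        pos = np.array([[5.0, 5.0, 5.0], [5.0, 5.7, 5.0]])
        cfg = m.Configuration(positions=pos, kinds=np.array([1, 1]),
                              molecules=[[0, 1]], box=np.array([10.0, 10.0, 10.0]))
        eta_max = m.max_admissible_strain(cfg, "y", ff)
        assert eta_max == pytest.approx(0.9 / 0.7 - 1.0, rel=1e-9)
        with pytest.raises(FeneDomainError):
            m.rescale_axial(cfg, eta_max + 0.01, "y", ff)
        m.rescale_axial(cfg, eta_max - 0.01, "y", ff)  # inside the domain: fine

    def test_vertical_chains_unconstrained_laterally(self, small_bilayer, ff):
        # straight-built chains have no lateral bond projection
        assert m.max_admissible_strain(small_bilayer, "y", ff) == np.inf


@pytest.fixture(scope="module")
def equilibrated(tri_network):
    from dataclasses import replace
    cfg = tri_network.to_configuration()
    ff = tri_network.forcefield()
    s = replace(NET_SETTINGS, sweeps=3000, seed=11)
    out, _ = m.run_mc(cfg, NET_PHASE, s, ff)
    return out, ff


class TestProtocolOnNetwork:
    def test_static_minimisation_oracle(self, tri_network):
        # continuum elasticity of the central-force triangular lattice
        nu = m.static_poisson_ratio(tri_network, eta=0.01)
        assert nu == pytest.approx(1.0 / 3.0, abs=0.01)

    def test_strained_axis_held_fixed(self, equilibrated):
        cfg, ff = equilibrated
        from dataclasses import replace
        s = replace(NET_SETTINGS, seed=3)
        res = m.measure_poisson(cfg, NET_PHASE, 0.05, "y", relax_sweeps=400,
                                anneal_sweeps=0, burn_in=200, pre_sweeps=300,
                                settings=s, ff=ff)
        # the y-length never moves after the rescale: no 'y' trace exists
        assert all(not key.startswith("y") for key in res.nu)

    def test_zero_strain_control(self, equilibrated):
        cfg, ff = equilibrated
        from dataclasses import replace
        s = replace(NET_SETTINGS, seed=17)
        res = m.measure_poisson(cfg, NET_PHASE, 0.0, "y", relax_sweeps=4000,
                                anneal_sweeps=0, burn_in=1000, pre_sweeps=2000,
                                settings=s, ff=ff)
        est, err = res.nu["xy"]
        assert abs(est) < max(4 * err, 0.01)

    def test_protocol_recovers_network_poisson_ratio(self, equilibrated):
        cfg, ff = equilibrated
        from dataclasses import replace
        s = replace(NET_SETTINGS, seed=23)
        res = m.measure_poisson(cfg, NET_PHASE, 0.05, "y", relax_sweeps=8000,
                                anneal_sweeps=0, burn_in=3000, pre_sweeps=2000,
                                settings=s, ff=ff)
        est, err = res.nu["xy"]
        assert est == pytest.approx(1.0 / 3.0, abs=0.05)

    def test_result_summary_renders(self, equilibrated):
        cfg, ff = equilibrated
        from dataclasses import replace
        s = replace(NET_SETTINGS, seed=29)
        res = m.measure_poisson(cfg, NET_PHASE, 0.05, "y", relax_sweeps=600,
                                anneal_sweeps=0, burn_in=300, pre_sweeps=300,
                                settings=s, ff=ff)
        text = res.summary()
        assert "eta=0.05" in text and "nu_xy" in text
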