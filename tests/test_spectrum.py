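"""Height field, power spectrum, and Helfrich fit against exact oracles."""
import numpy as np
import pytest

import memelast as m
from memelast.spectrum import (SpectrumError, average_power, bin_radially,
                               fit_helfrich, height_field, power_spectrum)


class TestHeightField:
    def test_flat_bilayer_is_zero(self, small_bilayer):
        hf = height_field(small_bilayer, spacing=2.0)
        np.testing.assert_allclose(hf.h, 0.0, atol=1e-10)

    def test_rigid_shift_invariance(self, small_bilayer):
        hf0 = height_field(small_bilayer, spacing=2.0)
        shifted = small_bilayer.copy()
        shifted.positions[:, 2] += 2.7
        shifted.wrap()
        hf1 = height_field(shifted, spacing=2.0)
        np.testing.assert_allclose(hf1.h, hf0.h, atol=1e-9)

    def test_corrugated_bilayer_recovers_cosine(self):
        # displace every lipid rigidly by A cos(2 pi x / Lx)
        cfg = m.build_bilayer(16, 16, "fluid", seed=0, solvent_density=0.0)
        A = 0.8
        Lx = cfg.box[0]
        for mol in cfg.lipids:
            mol = np.asarray(mol)
            x = cfg.positions[mol[0], 0]
            cfg.positions[mol, 2] += A * np.cos(2 * np.pi * x / Lx)
        cfg.wrap()
        hf = height_field(cfg, spacing=2.0)
        nx = hf.h.shape[0]
        x_cells = (np.arange(nx) + 0.5) * (Lx / nx)
        # cells collect lipids at discrete lattice x; compare against the
        # cosine evaluated at the lipid positions cell-averaged
        expected = np.cos(2 * np.pi * x_cells / Lx)
        got = hf.h.mean(axis=1)
        corr = np.corrcoef(expected, got)[0, 1]
        assert corr > 0.99
        assert np.abs(got).max() == pytest.approx(A, rel=0.15)

    def test_rupture_detection(self, small_bilayer):
        with pytest.raises(SpectrumError):
            height_field(small_bilayer, spacing=0.3)  # grid far finer than lipids


class TestPowerSpectrum:
    def test_zero_field_zero_power(self):
        hf = m.HeightField(h=np.zeros((8, 8)), spacing=2.0, box=(16.0, 16.0))
        ps = power_spectrum(hf)
        assert (ps["power"] == 0).all()
        assert (ps["q"] > 0).all()   # zero mode excluded

    def test_cosine_mode_amplitude(self):
        L, n, A = 64.0, 32, 1.7
        a = L / n
        x = np.arange(n) * a
        h = A * np.cos(2 * np.pi * x / L)[:, None] * np.ones((1, n))
        h -= h.mean()
        ps = power_spectrum(m.HeightField(h=h, spacing=a, box=(L, L)))
        top = ps.nlargest(2, "power")
        expected = (a * a * A * n * n / 2) ** 2   # analytic DFT of a cosine
        np.testing.assert_allclose(top["power"], expected, rtol=1e-10)
        np.testing.assert_allclose(np.abs(top["qx"]), 2 * np.pi / L, atol=1e-12)
        rest = ps.drop(top.index)
        assert rest["power"].max() < expected * 1e-20

    def test_parseval_identity(self):
        rng = np.random.default_rng(3)
        h = rng.standard_normal((16, 16))
        h -= h.mean()
        hf = m.HeightField(h=h, spacing=2.0, box=(32.0, 32.0))
        ps = power_spectrum(hf)
        lhs = ps["power"].sum() / (32.0 * 32.0)
        rhs = hf.cell_area * (h ** 2).sum()
        assert lhs == pytest.approx(rhs, rel=1e-10)

    def test_white_noise_spectrum_flat(self):
        rng = np.random.default_rng(8)
        n, L, sd = 32, 64.0, 0.5
        fields = [m.HeightField(h=(lambda x: x - x.mean())(sd * rng.standard_normal((n, n))),
                                spacing=L / n, box=(L, L)) for _ in range(200)]
        ps = average_power(fields)
        a = L / n
        expected = (a * a) ** 2 * n * n * sd ** 2   # i.i.d. noise: constant power
        assert ps["power"].mean() == pytest.approx(expected, rel=0.05)
        assert ps["power"].std() / ps["power"].mean() < 0.15


class TestHelfrichFit:
    def test_recovers_known_rigidity(self):
        fields = m.make_helfrich_ensemble(5.2, 0.0, 1.3, 128.0, 64, 500, seed=42)
        fit = fit_helfrich(average_power(fields), T=1.3)
        assert fit.ok
        assert fit.k_c == pytest.approx(5.2, rel=0.10)
        # tensionless ensemble: intercept consistent with zero
        assert abs(fit.sigma_tension) < 3 * fit.sigma_stderr

    def test_default_window_and_binning(self):
        fields = m.make_helfrich_ensemble(7.6, 0.0, 1.3, 128.0, 64, 100, seed=1)
        modes = average_power(fields)
        binned = bin_radially(modes)
        fit = fit_helfrich(modes, T=1.3)
        assert fit.fit_window == (0.5, 1.0)
        assert (binned["qsq"].between(0.5, 1.0)).sum() >= 3

    def test_single_frame_flagged_undersampled(self):
        fields = m.make_helfrich_ensemble(5.2, 0.0, 1.3, 64.0, 32, 1, seed=0)
        fit = fit_helfrich(average_power(fields), T=1.3)
        assert not fit.ok and "under-sampled" in fit.message

    def test_flat_frames_zero_power_flagged(self):
        flat = [m.HeightField(h=np.zeros((32, 32)), spacing=2.0, box=(64.0, 64.0))
                for _ in range(5)]
        fit = fit_helfrich(average_power(flat), T=1.3)
        assert not fit.ok and "zero-power" in fit.message

    def test_too_few_bins_raises(self):
        fields = m.make_helfrich_ensemble(5.2, 0.0, 1.3, 64.0, 32, 2, seed=0)
        with pytest.raises(SpectrumError):
            fit_helfrich(average_power(fields), T=1.3, window=(0.99, 1.0))


class TestHelfrichSampler:
    def test_frames_real_and_mean_zero(self):
        fields = m.make_helfrich_ensemble(5.2, 0.5, 1.3, 64.0, 16, 3, seed=5)
        for f in fields:
            assert f.h.dtype == np.float64
            assert abs(f.h.mean()) < 1e-12

    def test_seed_determinism(self):
        a = m.make_helfrich_ensemble(5.2, 0.0, 1.3, 64.0, 16, 2, seed=9)
        b = m.make_helfrich_ensemble(5.2, 0.0, 1.3, 64.0, 16, 2, seed=9)
        np.testing.assert_array_equal(a[0].h, b[0].h)
        np.testing.assert_array_equal(a[1].h, b[1].h)

    def test_power_linear_in_temperature(self):
        # identical seed: doubling T doubles every mode power exactly
        a = m.make_helfrich_ensemble(5.2, 0.0, 1.0, 64.0, 16, 1, seed=2)[0]
        b = m.make_helfrich_ensemble(5.2, 0.0, 2.0, 64.0, 16, 1, seed=2)[0]
        pa = power_spectrum(a)["power"].to_numpy()
        pb = power_spectrum(b)["power"].to_numpy()
        mask = pa > 1e-12
        np.testing.assert_allclose(pb[mask] / pa[mask], 2.0, rtol=1e-9)

    def test_degenerate_parameters_rejected(self):
        with pytest.raises(ValueError):
            m.make_helfrich_ensemble(0.0, 0.0, 1.3, 64.0, 16, 1, seed=0)
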