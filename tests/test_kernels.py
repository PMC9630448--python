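"""Kernel maps, transfer functions and retrieval filters."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pbi.geometry import FrequencyGrid, ImagingGeometry, KernelChoice, MaterialOptics
from pbi.kernels import (
    beltran_retrieve,
    fractional_difference,
    gaussian_ctf,
    k_perp2_gpm,
    k_perp2_pm,
    phase_retrieve,
    transfer_function,
    transfer_ratio,
    transfer_table,
)

# index of the Nyquist column on the 8x8 unit grid: (kx, ky) = (pi, 0)
NYQ = (0, 4)


class TestFrequencyGrid:
    def test_negation_symmetry(self):
        g = FrequencyGrid(shape=(8, 6), pixel_size=2.5)
        for k, n in ((g.kx_1d, 6), (g.ky_1d, 8)):
            for i in range(1, n):
                if i != n // 2:  # unpaired Nyquist sample excluded
                    assert k[i] == pytest.approx(-k[n - i])

    def test_nyquist_bound_and_sign(self):
        g = FrequencyGrid(shape=(8, 8), pixel_size=0.5)
        assert np.all(np.abs(g.kx * g.pixel_size) <= np.pi + 1e-12)
        assert np.all(np.abs(g.ky * g.pixel_size) <= np.pi + 1e-12)
        assert g.kx_1d[4] == pytest.approx(np.pi / 0.5)  # even grid: +pi/W

    def test_material_consistency_enforced(self):
        with pytest.raises(ValueError, match="inconsistent"):
            MaterialOptics(
                delta=1e-7, beta=1e-9, mu=999.0, wavelength=5e-11, energy_keV=24.0
            )


class TestKernelMaps:
    def test_dc_and_nyquist_values(self, unit_grid):
        pm = k_perp2_pm(unit_grid)
        gpm = k_perp2_gpm(unit_grid)
        assert pm[0, 0] == 0.0
        assert gpm[0, 0] == 0.0
        assert pm[NYQ] == pytest.approx(np.pi**2)
        assert gpm[NYQ] == pytest.approx(4.0)  # -2(cos pi + cos 0 - 2)
        # maxima at the DFT corner
        assert pm.max() == pm[4, 4]
        assert gpm.max() == gpm[4, 4] == pytest.approx(8.0)

    def test_transpose_symmetry(self):
        g = FrequencyGrid(shape=(8, 8), pixel_size=1.0)
        assert np.allclose(k_perp2_pm(g), k_perp2_pm(g).T)
        assert np.allclose(k_perp2_gpm(g), k_perp2_gpm(g).T)

    def test_taylor_convergence_near_dc(self):
        # cos kernel matches k^2 to < 1e-6 relative at W k = 1e-3
        w = 1.0
        k = 1e-3
        gpm = (-2.0 / w**2) * (np.cos(w * k) + 1.0 - 2.0)
        assert gpm == pytest.approx(k**2, rel=1e-6)

    def test_gpm_never_exceeds_pm(self):
        g = FrequencyGrid(shape=(33, 64), pixel_size=0.7)
        assert np.all(k_perp2_gpm(g) <= k_perp2_pm(g) + 1e-15)


class TestTransferFunctions:
    def test_dc_passthrough_and_range(self, unit_grid):
        h = transfer_function(unit_grid, delta=10.0, mu=1.0, distance=1.0)
        assert h[0, 0] == 1.0
        assert np.all((h > 0) & (h <= 1))

    def test_printed_nyquist_values(self, unit_grid):
        # delta*Delta/(mu W^2) = 10 at (kx, ky) = (pi, 0)
        h_gpm = transfer_function(unit_grid, 10.0, 1.0, 1.0, KernelChoice.GPM)
        h_pm = transfer_function(unit_grid, 10.0, 1.0, 1.0, KernelChoice.PM)
        assert h_gpm[NYQ] == pytest.approx(1.0 / 41.0)
        assert h_pm[NYQ] == pytest.approx(1.0 / (1.0 + 10.0 * np.pi**2))

    def test_zero_delta_is_identity(self, unit_grid):
        assert np.allclose(transfer_function(unit_grid, 0.0, 1.0, 1.0), 1.0)

    def test_zero_mu_rejected(self, unit_grid):
        with pytest.raises(ValueError, match="mu"):
            transfer_function(unit_grid, 1.0, 0.0, 1.0)

    def test_ratio_and_fractional_difference(self, unit_grid):
        r = transfer_ratio(unit_grid, 10.0, 1.0, 1.0)
        d = fractional_difference(unit_grid, 10.0, 1.0, 1.0)
        assert r[0, 0] == pytest.approx(1.0)
        assert d[0, 0] == pytest.approx(0.0)
        expected = (1.0 + 10.0 * np.pi**2) / 41.0
        assert r[NYQ] == pytest.approx(expected)  # ~2.4316
        assert d[NYQ] == pytest.approx(expected - 1.0)  # ~1.4316
        assert np.all(r >= 1.0 - 1e-15)
        assert np.all(d >= -1e-15)

    def test_ratio_monotone_along_axis(self):
        # brute-force scan on a dense 1-D line
        table = transfer_table(1.0, 10.0, 1.0, 1.0, direction="axis", n=2048)
        assert np.all(np.diff(table["R"]) >= -1e-12)

    def test_diagonal_abscissa_extends_past_pi(self):
        table = transfer_table(1.0, 10.0, 1.0, 1.0, direction="diagonal", n=64)
        assert table["k_normalized"][-1] == pytest.approx(np.pi * np.sqrt(2.0))

    def test_blurred_difference_bounded_by_unblurred(self, unit_grid):
        d = fractional_difference(unit_grid, 10.0, 1.0, 1.0)
        dbar = fractional_difference(unit_grid, 10.0, 1.0, 1.0, psf_fwhm_px=3.0)
        assert np.all(dbar <= d + 1e-15)
        assert np.allclose(
            dbar, d * gaussian_ctf(unit_grid, 3.0), atol=1e-15
        )  # denominator is the unblurred H_PM, so D-bar = G * D


class TestGaussianCTF:
    def test_identity_cases(self, unit_grid):
        assert np.allclose(gaussian_ctf(unit_grid, 0.0), 1.0)
        assert gaussian_ctf(unit_grid, 2.0)[0, 0] == 1.0

    def test_wider_psf_attenuates_more(self, unit_grid):
        g1 = gaussian_ctf(unit_grid, 1.0)
        g3 = gaussian_ctf(unit_grid, 3.0)
        nonzero = k_perp2_pm(unit_grid) > 0
        assert np.all(g3[nonzero] < g1[nonzero])

    def test_matches_real_space_gaussian_transform(self):
        # DFT of the sampled unit-integral Gaussian ~ analytic CTF
        n, w, fwhm = 256, 1.0, 4.0
        sigma = fwhm / (2.0 * np.sqrt(2.0 * np.log(2.0)))
        x = np.arange(n) - n // 2
        kernel1d = np.exp(-(x**2) / (2 * sigma**2))
        kernel = np.outer(kernel1d, kernel1d)
        kernel /= kernel.sum()
        ctf_num = np.abs(np.fft.fft2(np.fft.ifftshift(kernel)))
        g = FrequencyGrid(shape=(n, n), pixel_size=w)
        # sampled-Gaussian DFT differs from the continuous transform only by
        # frequency aliasing, ~1e-6 near Nyquist at this width
        assert np.allclose(ctf_num, gaussian_ctf(g, fwhm), atol=5e-6)


def _dft_oracle_filter(image, coeff, kernel):
    """O(N^4) direct Fourier sum, independent of scipy.fft."""
    n0, n1 = image.shape
    j0 = np.arange(n0)
    j1 = np.arange(n1)
    f0 = np.exp(-2j * np.pi * np.outer(j0, j0) / n0)
    f1 = np.exp(-2j * np.pi * np.outer(j1, j1) / n1)
    spec = f0 @ image.astype(complex) @ f1
    ky = 2 * np.pi * np.where(j0 <= n0 // 2, j0, j0 - n0) / n0
    kx = 2 * np.pi * np.where(j1 <= n1 // 2, j1, j1 - n1) / n1
    if kernel is KernelChoice.PM:
        k2 = ky[:, None] ** 2 + kx[None, :] ** 2
    else:
        k2 = -2.0 * (np.cos(ky)[:, None] + np.cos(kx)[None, :] - 2.0)
    spec /= 1.0 + coeff * k2
    out = f0.conj() @ spec @ f1.conj() / (n0 * n1)
    return out.real


class TestPhaseRetrieve:
    def test_uniform_image_maps_to_unity(self, unit_material, geometry_unit):
        img = np.full((8, 8), 3.7)
        out = phase_retrieve(img, 3.7, unit_material, geometry_unit)
        assert np.allclose(out, 1.0, atol=1e-12)

    def test_zero_delta_identity(self, geometry_unit):
        mat = MaterialOptics.from_delta_mu(0.0, 1.0, 24.0)
        img = np.random.default_rng(0).uniform(0.5, 1.5, (8, 8))
        assert np.allclose(phase_retrieve(img, 1.0, mat, geometry_unit), img, atol=1e-13)

    @pytest.mark.parametrize("kernel", [KernelChoice.PM, KernelChoice.GPM])
    def test_against_direct_dft_oracle(self, kernel, unit_material, geometry_unit, rng):
        img = rng.uniform(0.5, 2.0, (8, 8))
        got = phase_retrieve(img, 1.0, unit_material, geometry_unit, kernel=kernel)
        want = _dft_oracle_filter(img, 10.0, kernel)
        assert np.max(np.abs(got - want)) < 1e-10

    def test_linearity(self, unit_material, geometry_unit, rng):
        x = rng.uniform(0.5, 1.5, (8, 8))
        y = rng.uniform(0.5, 1.5, (8, 8))
        a, b = 0.3, 1.7
        lhs = phase_retrieve(a * x + b * y, 1.0, unit_material, geometry_unit)
        rhs = a * phase_retrieve(x, 1.0, unit_material, geometry_unit) + b * phase_retrieve(
            y, 1.0, unit_material, geometry_unit
        )
        assert np.max(np.abs(lhs - rhs)) < 1e-12

    def test_mean_preserved_exactly(self, unit_material, geometry_unit, rng):
        img = rng.uniform(0.5, 1.5, (8, 8))
        out = phase_retrieve(img, 1.0, unit_material, geometry_unit)
        assert out.mean() == pytest.approx(img.mean(), abs=1e-13)

    def test_nonpositive_pixels_rejected_then_repaired(self, unit_material, geometry_unit):
        img = np.ones((8, 8))
        img[3, 3] = -1.0
        with pytest.raises(ValueError, match="non-positive"):
            phase_retrieve(img, 1.0, unit_material, geometry_unit)
        out = phase_retrieve(img, 1.0, unit_material, geometry_unit, repair=True)
        assert np.all(np.isfinite(out))

    def test_i0_map_shape_mismatch(self, unit_material, geometry_unit):
        with pytest.raises(ValueError, match="shape"):
            phase_retrieve(np.ones((8, 8)), np.ones((4, 4)), unit_material, geometry_unit)

    def test_pad_mode_close_to_unpadded_on_periodic_input(self, unit_material, geometry_unit):
        img = np.ones((8, 8))
        out = phase_retrieve(img, 1.0, unit_material, geometry_unit, pad=True)
        assert np.allclose(out, 1.0, atol=1e-10)


class TestBeltranRetrieve:
    def test_equal_deltas_identity(self, geometry_unit, rng):
        m1 = MaterialOptics.from_delta_mu(2.0, 1.0, 24.0)
        m2 = MaterialOptics.from_delta_mu(2.0, 3.0, 24.0)
        img = rng.uniform(0.5, 1.5, (8, 8))
        assert np.allclose(beltran_retrieve(img, 1.0, m1, m2, geometry_unit), img, atol=1e-13)

    def test_vacuum_reduces_to_single_material(self, geometry_unit, rng, water):
        vac = MaterialOptics(0.0, 0.0, 0.0, wavelength=water.wavelength, energy_keV=24.0)
        img = rng.uniform(0.5, 1.5, (8, 8))
        two = beltran_retrieve(img, 1.0, vac, water, geometry_unit)
        one = phase_retrieve(img, 1.0, water, geometry_unit)
        assert np.max(np.abs(two - one)) < 1e-13

    def test_degenerate_pair_rejected(self, geometry_unit):
        m = MaterialOptics.from_delta_mu(1.0, 2.0, 24.0)
        with pytest.raises(ValueError, match="degenerate"):
            beltran_retrieve(np.ones((8, 8)), 1.0, m, m, geometry_unit)

    def test_kernel_variants_share_mean(self, geometry_unit, rng):
        m1 = MaterialOptics.from_delta_mu(1.0, 1.0, 24.0)
        m2 = MaterialOptics.from_delta_mu(5.0, 3.0, 24.0)
        img = rng.uniform(0.5, 1.5, (8, 8))
        pm = beltran_retrieve(img, 1.0, m1, m2, geometry_unit, kernel=KernelChoice.PM)
        gpm = beltran_retrieve(img, 1.0, m1, m2, geometry_unit, kernel=KernelChoice.GPM)
        assert pm.mean() == pytest.approx(gpm.mean(), abs=1e-12)
        assert not np.allclose(pm, gpm)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    a=st.floats(min_value=1e-3, max_value=1e3),
    wkx=st.floats(min_value=-np.pi, max_value=np.pi),
    wky=st.floats(min_value=-np.pi, max_value=np.pi),
)
def test_gpm_dominance_property(a, wkx, wky):
    """Inside the Nyquist square the discrete kernel never exceeds the
    continuous one, so H_GPM >= H_PM and the fractional difference >= 0."""
    k2_pm = wkx**2 + wky**2
    k2_gpm = -2.0 * (np.cos(wkx) + np.cos(wky) - 2.0)
    assert k2_gpm <= k2_pm + 1e-12
    h_pm = 1.0 / (1.0 + a * k2_pm)
    h_gpm = 1.0 / (1.0 + a * k2_gpm)
    assert h_gpm >= h_pm - 1e-15
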