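"""Leaf plate model, four-stream canopy model and band convolution."""

import numpy as np
import pytest

from defolicarbon.radiative_transfer import (
    WAVELENGTHS,
    CanopyParams,
    LeafParams,
    SpectralResponse,
    SpectralSample,
    band_convolve,
    build_lut,
    default_soil_spectrum,
    gaussian_srf,
    prospect_leaf,
    sail_canopy,
)

I670 = int(670 - WAVELENGTHS[0])
I800 = int(800 - WAVELENGTHS[0])


class TestLeafModel:
    def test_no_absorbers_conserves_energy(self):
        """With all pigment/water/matter contents zero the plate stack only
        scatters, so R + T stays essentially 1 everywhere."""
        leaf = prospect_leaf(LeafParams(cab=0, car=0, cbrown=0, cw=0, cm=0))
        total = leaf.reflectance + leaf.transmittance
        assert np.all(total > 0.95)

    def test_default_leaf_red_below_nir(self, default_leaf):
        """Chlorophyll absorbs in the red: with the fixed leaf inputs the
        670 nm reflectance sits well below 800 nm."""
        assert default_leaf.reflectance[I670] < default_leaf.reflectance[I800]

    def test_more_chlorophyll_darkens_red(self):
        low = prospect_leaf(LeafParams(cab=40.0))
        high = prospect_leaf(LeafParams(cab=80.0))
        assert high.reflectance[I670] < low.reflectance[I670]

    def test_structure_parameter_below_one_rejected(self):
        with pytest.raises(ValueError):
            LeafParams(n_layers=0.9)

    def test_energy_bound_over_parameter_ranges(self):
        """R + T <= 1 must hold for random draws across the allowed leaf
        parameter ranges."""
        rng = np.random.default_rng(7)
        for _ in range(100):
            params = LeafParams(
                n_layers=rng.uniform(1.5, 3.0),
                cab=rng.uniform(10.0, 80.0),
                car=rng.uniform(0.0, 20.0),
                cbrown=rng.uniform(0.0, 1.0),
                cw=rng.uniform(0.001, 0.03),
                cm=rng.uniform(0.002, 0.02),
            )
            leaf = prospect_leaf(params)
            assert np.all(leaf.reflectance + leaf.transmittance <= 1.0 + 1e-9)


class TestCanopyModel:
    def test_empty_canopy_returns_soil_exactly(self, default_leaf):
        soil = default_soil_spectrum()
        out = sail_canopy(default_leaf, CanopyParams(lai=0.0))
        np.testing.assert_array_equal(out.reflectance, soil)

    def test_red_darkens_and_nir_brightens_with_lai(self, default_leaf):
        red, nir = [], []
        for lai in range(1, 7):
            r = sail_canopy(default_leaf, CanopyParams(lai=float(lai))).reflectance
            red.append(r[I670])
            nir.append(r[I800])
        assert np.all(np.diff(red) <= 1e-9)
        assert np.all(np.diff(nir) >= -1e-9)

    def test_output_is_physical(self, default_leaf):
        r = sail_canopy(default_leaf, CanopyParams(lai=3.0)).reflectance
        assert np.all(r >= 0.0) and np.all(r <= 1.0)

    def test_dense_canopy_masks_soil(self, default_leaf):
        """At LAI 8 a +-0.1 soil perturbation moves canopy NIR by < 0.01."""
        soil = default_soil_spectrum()
        up = sail_canopy(
            default_leaf, CanopyParams(lai=8.0, soil_reflectance=np.clip(soil + 0.1, 0, 1))
        ).reflectance
        down = sail_canopy(
            default_leaf, CanopyParams(lai=8.0, soil_reflectance=np.clip(soil - 0.1, 0, 1))
        ).reflectance
        assert abs(up[I800] - down[I800]) < 0.01

    def test_angle_validation(self):
        with pytest.raises(ValueError):
            CanopyParams(tts=95.0)
        with pytest.raises(ValueError):
            CanopyParams(lai=9.0)


class TestBandConvolution:
    def test_constant_spectrum_maps_to_itself(self, srf):
        spectrum = SpectralSample(reflectance=np.full_like(WAVELENGTHS, 0.3))
        for value in band_convolve(spectrum, srf).values():
            assert value == pytest.approx(0.3, abs=1e-12)

    def test_delta_response_picks_single_wavelength(self):
        rho = np.linspace(0.0, 1.0, WAVELENGTHS.size)
        psi = np.zeros_like(WAVELENGTHS)
        psi[500] = 1.0
        out = band_convolve(
            SpectralSample(reflectance=rho), SpectralResponse(bands={"x": psi})
        )
        assert out["x"] == pytest.approx(rho[500])

    def test_boxcar_weighted_mean_analytic(self):
        """Boxcar over 600-700 nm of rho = lambda/2500 averages to 0.26."""
        rho = WAVELENGTHS / 2500.0
        psi = ((WAVELENGTHS >= 600) & (WAVELENGTHS <= 700)).astype(float)
        out = band_convolve(
            SpectralSample(reflectance=rho), SpectralResponse(bands={"box": psi})
        )
        assert out["box"] == pytest.approx(650.0 / 2500.0, abs=1e-12)

    def test_all_zero_response_rejected(self):
        with pytest.raises(ValueError):
            SpectralResponse(bands={"bad": np.zeros_like(WAVELENGTHS)})

    def test_agrees_with_trapezoid_oracle(self):
        """Weighted sum vs independent trapezoid integration on random
        smooth spectra and Gaussian responses."""
        rng = np.random.default_rng(3)
        for _ in range(10):
            rho = np.clip(
                0.3
                + 0.2 * np.sin(WAVELENGTHS / rng.uniform(80, 300))
                + rng.normal(0, 0.02, WAVELENGTHS.size),
                0,
                1,
            )
            psi = gaussian_srf(rng.uniform(600, 2200), rng.uniform(20, 120))
            got = band_convolve(
                SpectralSample(reflectance=rho), SpectralResponse(bands={"b": psi})
            )["b"]
            want = np.trapezoid(rho * psi, WAVELENGTHS) / np.trapezoid(psi, WAVELENGTHS)
            assert got == pytest.approx(want, abs=1e-6)


class TestLookupTable:
    def test_single_zero_entry_equals_convolved_soil(self, srf):
        lut = build_lut(np.array([0.0]), srf=srf)
        soil_bands = band_convolve(SpectralSample(reflectance=default_soil_spectrum()), srf)
        for j, b in enumerate(lut.bands):
            assert lut.reflectance[0, j] == pytest.approx(soil_bands[b], abs=1e-12)

    def test_shape_and_ordering(self, lut_005):
        assert lut_005.lai.size == 161
        assert np.all(np.diff(lut_005.lai) > 0)

    def test_red_column_decreases_with_lai(self, lut_005):
        red = lut_005.reflectance[:, lut_005.bands.index("red")]
        # non-increasing up to single-scattering saturation noise (the
        # hotspot term creeps up by ~1e-6 per step once the canopy is opaque)
        assert np.all(np.diff(red) <= 1e-5)

    def test_grid_validation(self):
        with pytest.raises(ValueError):
            build_lut(np.array([0.0, 9.0]))
        with pytest.raises(ValueError):
            build_lut(np.array([1.0, 0.5]))
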