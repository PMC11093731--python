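"""Scene generator: land cover, phenology truth, rendering, meteorology."""

import numpy as np
import pytest

from defolicarbon.lai_retrieval import SEASON_END_DOY, SEASON_START_DOY
from defolicarbon.radiative_transfer import forward_bands, prospect_leaf, sentinel2_like_srf
from defolicarbon.synthetic_scene import (
    CLASS_NAMES,
    SceneConfig,
    make_ec_gpp,
    make_lulc_map,
    make_meteo,
    make_phenology,
    render_reflectance,
)


def _config(**kw):
    defaults = dict(n_rows=10, n_cols=10, seed=7)
    defaults.update(kw)
    return SceneConfig(**defaults)


class TestLULC:
    def test_degenerate_fractions_fill_scene(self):
        cfg = _config(class_fractions={"deciduous": 1.0})
        lulc = make_lulc_map(cfg)
        assert lulc.mask("deciduous").all()

    def test_even_split_is_exact(self):
        cfg = _config(class_fractions={"deciduous": 0.5, "conifer": 0.5})
        lulc = make_lulc_map(cfg)
        assert lulc.mask("deciduous").sum() == 50
        assert lulc.mask("conifer").sum() == 50

    def test_deterministic_for_fixed_seed(self):
        cfg = _config()
        np.testing.assert_array_equal(make_lulc_map(cfg).labels, make_lulc_map(cfg).labels)

    def test_fractions_within_one_pixel(self):
        cfg = _config(n_rows=17, n_cols=13)
        lulc = make_lulc_map(cfg)
        n = 17 * 13
        for cls, frac in cfg.class_fractions.items():
            assert abs(lulc.mask(cls).sum() - frac * n) <= 1.0

    def test_bad_fractions_rejected(self):
        with pytest.raises(ValueError):
            _config(class_fractions={"deciduous": 0.6, "conifer": 0.6})


class TestPhenology:
    cfg = _config()

    def test_non_vegetated_classes_are_zero(self):
        assert np.all(make_phenology("water", "normal", self.cfg).lai == 0)
        assert np.all(make_phenology("urban", "infestation", self.cfg).lai == 0)

    def test_conifer_untouched_by_infestation(self):
        normal = make_phenology("conifer", "normal", self.cfg).lai
        infested = make_phenology("conifer", "infestation", self.cfg).lai
        np.testing.assert_array_equal(normal, infested)

    @pytest.mark.parametrize("cls,target", [("deciduous", 0.25), ("mixed", 0.17)])
    def test_prescribed_seasonal_depression(self, cls, target):
        doy = np.arange(1, 366)
        sel = (doy >= SEASON_START_DOY) & (doy <= SEASON_END_DOY)
        normal = make_phenology(cls, "normal", self.cfg).lai[sel].mean()
        infested = make_phenology(cls, "infestation", self.cfg).lai[sel].mean()
        assert infested / normal == pytest.approx(1.0 - target, abs=0.01)

    def test_trajectory_rejoins_normal_outside_notch(self):
        normal = make_phenology("deciduous", "normal", self.cfg).lai
        infested = make_phenology("deciduous", "infestation", self.cfg).lai
        doy = np.arange(1, 366)
        outside = (doy <= self.cfg.infestation_onset) | (doy >= self.cfg.infestation_recovery)
        np.testing.assert_allclose(infested[outside], normal[outside], atol=1e-12)
        inside = (doy > self.cfg.infestation_onset + 10) & (
            doy < self.cfg.infestation_recovery - 10
        )
        assert np.all(infested[inside] < normal[inside])

    def test_bounds_and_validation(self):
        for cls in CLASS_NAMES:
            lai = make_phenology(cls, "normal", self.cfg).lai
            assert np.all((lai >= 0) & (lai <= 8))
        with pytest.raises(ValueError):
            make_phenology("savanna", "normal", self.cfg)
        with pytest.raises(ValueError):
            make_phenology("deciduous", "drought", self.cfg)


@pytest.fixture(scope="module")
def forward():
    leaf = prospect_leaf()
    srf = sentinel2_like_srf()
    return lambda lai: forward_bands(lai, _leaf_spectrum=leaf, srf=srf)


class TestRendering:
    bands = ("blue", "red", "nir", "swir")

    def test_zero_noise_equals_forward_simulation(self, forward):
        cfg = _config(n_rows=2, n_cols=2, class_fractions={"deciduous": 1.0})
        lulc = make_lulc_map(cfg)
        truth = {"deciduous": make_phenology("deciduous", "normal", cfg)}
        cube = render_reflectance(truth, lulc, np.array([180]), forward, self.bands, 0.0, 0)
        want = forward(truth["deciduous"].lai[179])
        for j, b in enumerate(self.bands):
            np.testing.assert_array_equal(cube.reflectance[0, :, :, j], want[b])

    def test_seeded_reproducibility(self, forward):
        cfg = _config(n_rows=3, n_cols=3)
        lulc = make_lulc_map(cfg)
        truth = {c: make_phenology(c, "normal", cfg) for c in cfg.class_fractions}
        doy = np.array([150, 200])
        c1 = render_reflectance(truth, lulc, doy, forward, self.bands, 0.01, 42)
        c2 = render_reflectance(truth, lulc, doy, forward, self.bands, 0.01, 42)
        np.testing.assert_array_equal(c1.reflectance, c2.reflectance)

    def test_noise_magnitude_monte_carlo(self, forward):
        """1000 pixels at fixed LAI: per-band sample sd within 15% of the
        requested 0.01."""
        cfg = SceneConfig(n_rows=20, n_cols=50, class_fractions={"deciduous": 1.0}, seed=3)
        lulc = make_lulc_map(cfg)
        truth = {"deciduous": make_phenology("deciduous", "normal", cfg)}
        cube = render_reflectance(truth, lulc, np.array([200]), forward, self.bands, 0.01, 5)
        sds = cube.reflectance[0].reshape(-1, 4).std(axis=0, ddof=1)
        assert np.all(np.abs(sds - 0.01) <= 0.15 * 0.01)

    def test_reflectance_clipped_to_physical_range(self, forward):
        cfg = _config(n_rows=4, n_cols=4)
        lulc = make_lulc_map(cfg)
        truth = {c: make_phenology(c, "normal", cfg) for c in cfg.class_fractions}
        cube = render_reflectance(truth, lulc, np.array([200]), forward, self.bands, 0.3, 1)
        assert np.all((cube.reflectance >= 0) & (cube.reflectance <= 1))


class TestMeteo:
    def test_zero_amplitude_no_noise_is_constant(self):
        cfg = _config(ta_amplitude=0.0)
        met = make_meteo(2020, cfg, with_noise=False)
        np.testing.assert_allclose(met["ta"], 10.6)

    def test_annual_mean_close_to_configured(self):
        met = make_meteo(2021, _config())
        assert met["ta"].mean() == pytest.approx(10.6, abs=0.3)

    def test_par_and_precip_non_negative(self):
        met = make_meteo(2022, _config())
        assert (met["par"] >= 0).all()
        assert (met["precip"] >= 0).all()
        assert met["vwc"].between(0, 1).all()

    def test_365_daily_records(self):
        met = make_meteo(2020, _config())
        assert len(met) == 365 and met["doy"].iloc[-1] == 365


class TestTowerGPP:
    def test_zero_noise_is_identity(self):
        truth = np.linspace(0, 12, 214)
        np.testing.assert_array_equal(make_ec_gpp(truth, 0.0, 1), truth)

    def test_all_zero_truth_stays_zero(self):
        out = make_ec_gpp(np.zeros(50), 1.0, 3)
        assert np.all(out == 0.0)

    def test_regression_slope_near_unity(self):
        """OLS of noisy tower GPP on truth at noise sd 1, n 214."""
        rng = np.random.default_rng(17)
        truth = np.clip(10 * np.sin(np.linspace(0, np.pi, 214)), 0, None) + 2.0
        noisy = make_ec_gpp(truth, 1.0, seed=31)
        slope = np.polyfit(truth, noisy, 1)[0]
        assert 0.9 <= slope <= 1.1

    def test_negative_truth_rejected(self):
        with pytest.raises(ValueError):
            make_ec_gpp(np.array([-1.0]), 0.5, 1)
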