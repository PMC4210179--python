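"""Light-field chain: solar geometry, clear sky, water column, PAR."""

import datetime as dt
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from seacanopy.bands import DirectionalRadiance, SpectralBands, ZenithGrid, to_par
from seacanopy.lightfield import (ShadingLevel, Site, WaterIOPs,
                                  apply_shading, azimuthal_average,
                                  clear_sky_radiance, compute_kd_par,
                                  diurnal_zeniths, propagate_water_column,
                                  refract_zenith, solar_position,
                                  top_of_canopy_radiance)

JURIEN = (-30.3095, 115.0072)
DATE = dt.date(2005, 4, 27)


def _oracle_declination(doy: int) -> float:
    """Independent low-precision ephemeris (Cooper's formula), degrees."""
    return 23.45 * math.sin(math.radians(360.0 * (284 + doy) / 365.0))


class TestSolarPosition:
    def test_equator_equinox_noon_overhead(self):
        """Sun passes within ~1 deg of the zenith (apparent solar noon may
        differ from clock noon by the equation of time)."""
        zeniths = [solar_position(0.0, 0.0, dt.date(2005, 3, 20), h,
                                  utc_offset=0.0)[0]
                   for h in np.arange(11.0, 13.0, 0.05)]
        assert min(zeniths) <= 1.0

    def test_diurnal_symmetry_about_solar_noon(self):
        hours, zens = diurnal_zeniths(*JURIEN[:1], DATE)
        assert np.allclose(zens, zens[::-1], atol=1e-12)

    def test_jurien_bay_noon_vs_independent_ephemeris(self):
        """Cross-check against Cooper declination; in-water angle via Snell.

        The refracted noon zenith (~31 deg) sits near the ~28 deg the study
        site's midday geometry implies once the air-water interface is
        accounted for.
        """
        _, zens = diurnal_zeniths(JURIEN[0], DATE)
        noon = float(zens.min())
        decl = _oracle_declination(DATE.timetuple().tm_yday)
        expected = abs(JURIEN[0] - decl)  # |lat - decl| at solar noon
        assert noon == pytest.approx(expected, abs=1.0)
        water = refract_zenith(noon)
        assert 28.0 <= water <= 33.0

    def test_latitude_bounds_rejected(self):
        with pytest.raises(ValueError):
            solar_position(95.0, 0.0, DATE, 12.0)


class TestClearSky:
    def test_sun_below_horizon_all_zero(self, bands, zgrid):
        rad = clear_sky_radiance(95.0, bands, zgrid)
        assert np.all(rad.radiance == 0)

    def test_direct_beam_bin_dominates(self, bands, zgrid):
        rad = clear_sky_radiance(40.0, bands, zgrid)
        e_bins = rad.radiance.sum(axis=1) * zgrid.cos_weight
        assert np.argmax(e_bins) == zgrid.bin_of(40.0)

    def test_band_grid_is_17x20nm(self, bands, zgrid):
        rad = clear_sky_radiance(40.0, bands, zgrid)
        assert rad.radiance.shape == (zgrid.n_bins, 17)
        assert bands.edges[0] == 400.0 and bands.edges[-1] == 740.0


class TestAzimuthalAverage:
    def test_uniform_input_is_identity(self, bands, zgrid):
        base = np.random.default_rng(0).uniform(0, 2, (zgrid.n_bins, bands.n))
        grid = np.repeat(base[:, None, :], 24, axis=1)
        out = azimuthal_average(grid, bands, zgrid)
        assert np.allclose(out.radiance, base)

    def test_planar_irradiance_conserved(self, bands, zgrid):
        rng = np.random.default_rng(1)
        grid = rng.uniform(0, 3, (zgrid.n_bins, 24, bands.n))
        out = azimuthal_average(grid, bands, zgrid)
        e_before = np.einsum("z,zab->b", zgrid.cos_weight, grid / 24.0)
        assert np.allclose(out.planar_irradiance(), e_before, rtol=1e-12)

    def test_single_azimuth_beam_redistributed(self, bands, zgrid):
        """A one-azimuth beam becomes a ring carrying the same E_d."""
        n_az = 24
        grid = np.zeros((zgrid.n_bins, n_az, bands.n))
        grid[5, 3, :] = 7.0
        out = azimuthal_average(grid, bands, zgrid)
        assert np.allclose(out.radiance[5], 7.0 / n_az)
        expected_ed = 7.0 / n_az * zgrid.cos_weight[5]
        assert np.allclose(out.planar_irradiance(), expected_ed)


class TestWaterColumn:
    def test_depth_zero_in_water_identity(self, bands, zgrid, iops):
        rad = clear_sky_radiance(40.0, bands, zgrid)
        out = propagate_water_column(rad, iops, 0.0, interface=False)
        assert np.allclose(out.radiance, rad.radiance, rtol=1e-12)

    def test_beer_lambert_scattering_free(self, bands, zgrid):
        """Pure absorption: each bin attenuates by exp(-a d / cos theta)."""
        a = np.linspace(0.05, 0.5, bands.n)
        iops = WaterIOPs.absorbing_only(a)
        rad = np.zeros((zgrid.n_bins, bands.n))
        rad[4] = 1.0
        rad = DirectionalRadiance(bands, zgrid, rad)
        depth = 3.0
        out = propagate_water_column(rad, iops, depth, interface=False)
        mu = math.cos(math.radians(zgrid.eff_zenith[4]))
        expected = np.exp(-a * depth / mu)
        assert np.allclose(out.radiance[4], expected, rtol=1e-9)
        mask = np.ones(zgrid.n_bins, dtype=bool)
        mask[4] = False
        assert np.all(out.radiance[mask] == 0)

    def test_reference_iops_kd_anchor(self, site, iops, bands, zgrid):
        """Packaged IOPs give k_d(PAR) = 0.20 +/- 0.02 /m over 0-4.5 m."""
        _, zens = diurnal_zeniths(site.latitude, site.date)
        sky = clear_sky_radiance(float(zens.min()), bands, zgrid)
        e = [propagate_water_column(sky, iops, z).par() for z in (0.0, 4.5)]
        kd = compute_kd_par(np.array([0.0, 4.5]), np.array(e))
        assert kd == pytest.approx(0.20, abs=0.02)

    def test_kd_increases_with_absorption(self, bands, zgrid, iops):
        sky = clear_sky_radiance(44.0, bands, zgrid)

        def kd_with(extra):
            w = WaterIOPs(iops.absorption + extra, iops.backscatter)
            e = [propagate_water_column(sky, w, z).par() for z in (0.0, 4.5)]
            return compute_kd_par(np.array([0.0, 4.5]), np.array(e))

        assert kd_with(0.05) > kd_with(0.0)


class TestKdRegression:
    def test_exact_exponential(self):
        z = np.array([0.0, 4.5])
        e = 100.0 * np.exp(-0.2 * z)
        assert compute_kd_par(z, e) == pytest.approx(0.2, abs=1e-12)

    def test_constant_profile_zero(self):
        assert compute_kd_par(np.array([0, 2, 4]), np.array([5.0, 5.0, 5.0])) == pytest.approx(0.0, abs=1e-12)

    def test_matches_independent_regression(self):
        rng = np.random.default_rng(3)
        z = np.array([0.0, 2.0, 4.5])
        e = 80.0 * np.exp(-0.31 * z) * np.exp(rng.normal(0, 0.05, 3))
        from scipy.stats import linregress
        expected = -linregress(z, np.log(e)).slope
        assert compute_kd_par(z, e) == pytest.approx(expected, abs=1e-9)

    def test_nonpositive_rejected(self):
        with pytest.raises(ValueError):
            compute_kd_par(np.array([0.0, 1.0]), np.array([1.0, 0.0]))


class TestShadingAndPar:
    def test_shading_identity_half_and_95(self, bands, zgrid):
        rad = clear_sky_radiance(40.0, bands, zgrid)
        assert np.allclose(apply_shading(rad, ShadingLevel(0.0)).radiance,
                           rad.radiance)
        assert np.allclose(apply_shading(rad, ShadingLevel(0.5)).radiance,
                           0.5 * rad.radiance)
        assert np.allclose(apply_shading(rad, ShadingLevel(0.95)).radiance,
                           0.05 * rad.radiance)

    def test_invalid_levels_rejected(self):
        for bad in (-0.1, 1.0, 1.5):
            with pytest.raises(ValueError):
                ShadingLevel(bad)

    def test_par_photon_energy_oracle(self, bands):
        e = np.zeros(bands.n)
        e[list(bands.centres).index(550.0)] = 1.0
        assert to_par(e, bands) == pytest.approx(4.598, abs=0.001)

    def test_par_flat_spectrum_integral_oracle(self, bands):
        e = np.where(bands.par_mask, 20.0, 0.0)  # 1 W/m2/nm over 400-700
        lam = np.linspace(400, 700, 3001)
        expected = np.trapezoid(0.0083593 * lam, lam)
        assert to_par(e, bands) == pytest.approx(expected, rel=0.005)

    def test_zero_spectrum(self, bands):
        assert to_par(np.zeros(bands.n), bands) == 0.0

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(s=st.floats(0.0, 0.99), c=st.floats(0.01, 10.0))
    def test_shading_par_commutation(self, s, c, bands, zgrid):
        """to_par(shade(r, s)) == (1-s) to_par(r), and linearity in c."""
        rad = clear_sky_radiance(40.0, bands, zgrid).scaled(c)
        shaded = apply_shading(rad, ShadingLevel(s))
        assert shaded.par() == pytest.approx((1 - s) * rad.par(), rel=1e-12)


def test_diurnal_symmetry_of_boundary_radiance(site, iops, bands, zgrid):
    """Mirrored hours yield identical top-of-canopy radiance distributions."""
    _, zens = diurnal_zeniths(site.latitude, site.date, 12)
    r1 = top_of_canopy_radiance(site, float(zens[2]), iops, bands, zgrid)
    r2 = top_of_canopy_radiance(site, float(zens[9]), iops, bands, zgrid)
    assert np.allclose(r1.radiance, r2.radiance, rtol=1e-9)
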